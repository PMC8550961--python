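"""Simulate a drift/admixture genotype panel with known ground truth.

Builds a three-population star with an outgroup, draws pseudo-haploid
calls and read counts for 60 individuals, and writes the panel in
EIGENSTRAT and VCF formats.
"""

from paleodrift import io
from paleodrift.simulate import star_scenario

panel = star_scenario(n_per_pop=15, n_admixed=15, n_sites=5000, seed=1)

calls = panel.calls
print(f"panel: {calls.n_samples} samples x {calls.n_sites} sites")
print(f"missing fraction: {(~calls.observed()).mean():.3f}")
print("ground-truth mixing vector of the first admixed individual:")
print(panel.q_true.loc["M000"].round(3).to_string())

io.write_eigenstrat(calls, "scratch_panel", groups=panel.meta["group"])
io.write_vcf(calls, "scratch_panel.vcf")
print("wrote scratch_panel.{geno,snp,ind} and scratch_panel.vcf")
# The q_true rows are the quantity every downstream inference is judged
# against: each row sums to one and gives the individual's ancestry shares.
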