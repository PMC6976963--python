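"""Filter allele-frequency trajectories for resistance association.

Simulates pooled read counts for a scenario with causal SNP clusters among
neutral loci, applies the variant QC (depth > 30 everywhere, minor-allele
support, polymorphism) and the banded trajectory filter, and prints the
hits with their five-stage frequency profiles.
"""

from poolcross import scan_trajectories, simulate_counts
from poolcross.scenarios import study_loci
from poolcross.simulate import SimConfig, run_design

loci = study_loci(
    n_neutral_snps=400, n_causal_snps=6, n_neutral_genes=0, n_causal_genes=0, seed=3
)
design = run_design(loci, SimConfig(seed=3))
counts = simulate_counts(design)

traj = scan_trajectories(counts)
hits = traj[traj["verdict"] != "none"]

print(f"{len(traj)} locus x line trajectories tested, {len(hits)} hits\n")
cols = ["locus_id", "line", "verdict", "f_F0", "f_F0_LD80", "f_F2", "f_F2_LD25", "f_F2_LD75"]
print(hits[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print(
    "\nA resistance-associated hit rises from F0 to the LD80 survivors by"
    "\nat least the band minimum (15 points for common alleles), falls after"
    "\nthe susceptible cross, and rises again with the F2 dose; deleterious"
    "\nalleles show the mirror-image trajectory."
)
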