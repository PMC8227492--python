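"""Canonical seed-site prediction on 3'-UTRs.

Derives the 8mer / 7mer-m8 / 7mer-A1 patterns from the miR-31-3p seed
(nucleotides 2-8) and scans synthetic UTRs, recovering the planted sites.
"""

from mirdupscreen import (
    MatureMiRNA,
    SequenceRecord,
    SimConfig,
    predict_targets,
    seed_patterns,
    simulate_utrs,
)
from mirdupscreen.synthetic import MIR31_3P

mirna = MatureMiRNA.from_name(
    "hsa-miR-31-3p", SequenceRecord("hsa-miR-31-3p", "", MIR31_3P)
)
print(f"mature sequence (DNA alphabet): {MIR31_3P}")
for site_type, pattern in seed_patterns(MIR31_3P).items():
    print(f"  {site_type:8s} target pattern: {pattern}")

cfg = SimConfig(n_genes=20, n_true_targets=8, utr_length=1500, seed=4,
                sites_per_target={"8mer": 1, "7mer-A1": 1})
utrs, truth = simulate_utrs(cfg, mirna)
prediction = predict_targets(utrs, mirna)

print(f"\nscanned {len(utrs)} UTRs; {len(prediction)} genes carry sites:")
for gene in sorted(prediction.genes):
    sites = prediction.sites_by_gene[gene]
    where = ", ".join(f"{s.site_type}@{s.start}" for s in sites)
    print(f"  {gene}: {len(sites)} sites ({where})")
print("\nplanted truth matches:", prediction.genes == truth.true_targets)
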