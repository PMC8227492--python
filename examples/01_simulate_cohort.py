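"""Generate a synthetic tumor cohort and inspect what was planted.

The generator emits every input the screen consumes — miRNA counts,
mature sequences, gene expression, 3'-UTRs with seed sites, and a clinical
table — together with the ground truth, so recovery can be scored exactly.
"""

from mirdupscreen import SimConfig, simulate_bundle

cfg = SimConfig(seed=1)
bundle = simulate_bundle(cfg)

print(f"cohort: {cfg.n_tumor} tumors, {cfg.n_normal} normals")
print(f"miRNA count matrix: {len(bundle.counts.feature_ids)} mature features")
print(f"gene expression: {bundle.expression.shape[0]} genes")
print(f"UTRs: {len(bundle.utrs)} records of {cfg.utr_length} nt")
print(f"clinical: {len(bundle.clinical)} patients, "
      f"{int(bundle.clinical.data['event'].sum())} events")
print()
print("planted duplex precursors:", sorted(bundle.truth.duplex_precursors))
print("planted true targets:     ", len(bundle.truth.true_targets))
print("planted prognostic genes: ", sorted(bundle.truth.prognostic_genes))
# Both arms of each planted precursor are up-regulated in tumors by
# 2^planted_log2fc; the prognostic genes carry a survival hazard for the
# below-median expression group.
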