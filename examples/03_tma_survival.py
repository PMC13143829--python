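"""ECM scoring of a multiplexed TMA cohort and survival stratification.

Generates a synthetic 198-patient cohort in which ECM-high patients carry a
3x hazard, applies the <100-cell exclusion, computes per-patient ECM
(0-5) and YAP classes, and compares survival with Kaplan-Meier + log-rank.
"""

from collmot.synthetic import SyntheticCohortSpec, make_tma_cohort
from collmot.tma import compare_survival, score_cohort

cohort = make_tma_cohort(SyntheticCohortSpec(n_patients=198, hazard_ratio=3.0, seed=42))
scored, report = score_cohort(cohort.cells, min_cells=100)

print(f"patients entering analysis : {report.n_retained} "
      f"({len(report.excluded_ids)} excluded by the <{report.min_cells}-cell rule)")
print("\nECM score distribution (points = markers above the cohort median):")
print(scored["ecm_score"].value_counts().sort_index().to_string())
print(f"\nECM-high patients: {(scored['ecm_group'] == 'high').sum()}, "
      f"ECM-low: {(scored['ecm_group'] == 'low').sum()}")

curves, lr = compare_survival(scored, cohort.survival, by="ecm_group")
for label, km in curves.items():
    print(f"  ECM-{label:4s}: median survival ~ "
          f"{km.time[km.survival <= 0.5][0] if (km.survival <= 0.5).any() else float('inf'):.0f} months")
print(f"\nlog-rank chi-square = {lr.statistic:.1f}, p = {lr.p_value:.2e}")
print("(small p: the ECM-high group dies significantly faster, as built"
      " into the generator)")
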