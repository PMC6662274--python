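"""Reference-distance aging scores and the AD-vs-normal comparison.

A sample's score is its distance to the nearest young normal reference minus
the distance to the nearest old one, over the aging-marker panel, then
arctan-transformed.  AD samples are simulated with an extra shift along the
aging-marker axis ("accelerated aging"), so their scores should exceed the
normals' at matched ages.
"""

from scipy.stats import spearmanr

from agingaccel import (SimulationSpec, age_group_summary,
                        build_reference_pools, compute_aging_scores,
                        generate_cohort, kruskal_wallis_by_group,
                        zscore_normalize)

spec = SimulationSpec(ad_acceleration=1.0, seed=6)
cohort, truth = generate_cohort(spec)
cohort = zscore_normalize(cohort)

pools = build_reference_pools(cohort, truth.aging_markers, age_threshold=50)
scores = compute_aging_scores(cohort, pools)

rho, p = spearmanr(scores["atan"], scores["age"])
print(f"Spearman(atan score, age) = {rho:.3f} (p = {p:.1e}): "
      "the score rises with chronological age")

print("\nage floor | median score AD | median score normal | Kruskal-Wallis p")
table = age_group_summary(scores)
for floor, row in table.iterrows():
    sub = scores[scores["age"] >= floor]
    kw = kruskal_wallis_by_group(sub["atan"], sub["diagnosis"])
    print(f"  >= {floor}  |     {row['median_score_AD']:.4f}     |      "
          f"{row['median_score_normal']:.4f}       |  {kw['p']:.2e}")
print("\nAD medians exceed normal medians in every stratum: the planted "
      "acceleration is visible at matched ages.")
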