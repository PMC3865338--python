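"""Where the picture-score variance goes.

Decomposes each picture-score's sum of squares into per-category SS plus the
within-picture category cross products, then reconciles both aggregation
modes against one shared total SS.  The within-picture cross products that
inflate the picture-score variances are exactly the terms that feed the
category-score covariances - the algebraic reason category-mode alpha is
higher whenever stories are internally consistent but pictures differ.
"""

import psemetrics as pm

t = pm.worked_example()
dec = pm.picture_ss_decomposition(t)
for p, pic in enumerate(dec.pictures):
    within = dec.category_ss[p].sum()
    print(f"picture {pic}: total SS {dec.total_ss[p]:.4f} = "
          f"within-category {within:.4f} + cross products "
          f"{dec.total_ss[p] - within:.4f}")
print(f"decomposition residual: {dec.residual:.2e}")

terms = pm.cross_level_terms(t)
print(f"\ntotal SS {terms.total_ss:.4f} = cell SS {terms.cell_ss:.4f}"
      f" + 2*({terms.within_picture_between_category:.4f}"
      f" [within picture, between category]"
      f" + {terms.within_category_between_picture:.4f}"
      f" [within category, between picture]"
      f" + {terms.between_both:.4f} [between both])")

gap = pm.alpha_gap_analysis(t)
print(f"\nalpha(category) - alpha(picture) = {gap.alpha_category:.3f}"
      f" - ({gap.alpha_picture:.3f}) = {gap.gap:.3f}")
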