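"""The minimal tensor that shows why item choice matters.

Builds the packaged 7-subject, 3-picture, 3-category demonstration tensor,
aggregates it into category-score and picture-score items, and prints both
intercorrelation matrices and alphas.  The subject totals are identical in
both modes, yet the category items correlate .84-1.00 while the picture
items correlate slightly negatively — so alpha is .95 in category mode and
-.48 in picture mode.
"""

import numpy as np

import psemetrics as pm

t = pm.worked_example()
cat = pm.to_category_items(t)
pic = pm.to_picture_items(t)

print("subject totals:", t.total_scores().tolist())
print("category items (columns):\n", cat.scores)
print("picture items (columns):\n", pic.scores)

print("\ncategory intercorrelations:\n",
      np.round(pm.covariance_summary(cat).correlation, 2))
print("picture intercorrelations:\n",
      np.round(pm.covariance_summary(pic).correlation, 2))

print(f"\nalpha (category items): {pm.alpha(cat):.3f}")
print(f"alpha (picture items):  {pm.alpha(pic):.3f}")
print("Same data, same totals - the aggregation mode alone flips the "
      "apparent reliability.")
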