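"""The full lower-bound family on a simulated Heckhausen-design study.

Simulates hope-of-success (5 main categories) and fear-of-failure (6 main
categories) codings for 35 subjects on six pictures, derives the ST/FT
weighting categories from the cross-scale rules, and prints every
coefficient (lambda_1..lambda_6, alpha/KR-20, omega_t) for the category,
picture and dichotomous item aggregations.
"""

import numpy as np

import psemetrics as pm
from psemetrics.synthetic import SimulationConfig, simulate_pse


def heckhausen_shaped(n_categories, scheme, seed):
    """Simulate one scale's main-category codings on the six-picture design."""
    sim = simulate_pse(SimulationConfig(
        n_subjects=35, n_pictures=6, n_categories=n_categories,
        cue_sd=1.0, sawtooth=0.5, seed=seed,
    ))
    return pm.ScoringTensor(
        sim.values, pictures=tuple("ABCDEF"),
        categories=scheme.main_categories, scale_id=scheme.scale_id,
    )


hs = heckhausen_shaped(5, pm.HS_SCHEME, seed=1963)
ff = heckhausen_shaped(6, pm.FF_SCHEME, seed=1964)
hs_w, ff_w = pm.attach_weighting(hs, ff)

reports = pm.reliability_report(hs_w, ff_w, include_weighting=True)
for (scale, mode), rep in reports.items():
    print(f"{scale:>2} / {mode:<11} items={rep.n_items:>2}  "
          f"l1={rep.lambda1:.2f} l2={rep.lambda2:.2f} "
          f"alpha={rep.alpha:.2f} l4max={rep.lambda4_max:.2f} "
          f"l5={rep.lambda5:.2f} l6={rep.lambda6:.2f} "
          f"omega={rep.omega_total:.2f}"
          f"{'  (alpha = KR-20)' if rep.is_kr20 else ''}")

s = pm.scale_scores(hs_w, ff_w)
print("\nfirst five subjects: HS", s.hs_total[:5], " FF", s.ff_total[:5],
      " net hope", s.net_hope[:5], " resultant", s.resultant[:5])
print("Categories-as-items and the dichotomous cells use the same totals as "
      "pictures-as-items; lambda_2 is always >= alpha (Guttman bound).")
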