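"""Sum-of-squares and covariance decompositions of nested PSE scores.

The picture-score of a story is a sum of category codings, so its sum of
squares splits exactly into the per-category sums of squares plus the
mean-deviation cross products of every category pair within that picture.
Summing over levels the same way shows that the total-test variance is shared
between the two item aggregations: what enters the picture-score *variances*
as within-picture category cross products enters the category-score
*covariances*, and vice versa.  That bookkeeping is why a tensor with high
within-picture category agreement but picture-to-picture instability yields a
high category-mode alpha and a low (often negative) picture-mode alpha.

All identities here are computed in sum-of-squares (SS) form — never divided
by N — so no variance-denominator convention can blur them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    ItemMatrix,
    ScoringTensor,
    to_category_items,
    to_picture_items,
)
from .reliability import alpha

__all__ = [
    "SSDecomposition",
    "CovarianceSumSummary",
    "CrossLevelTerms",
    "AlphaGapReport",
    "picture_ss_decomposition",
    "covariance_sum",
    "cross_level_terms",
    "alpha_gap_analysis",
]


def _ss(x: np.ndarray) -> float:
    """Sum of squared deviations from the column mean."""
    d = x - x.mean(axis=0)
    return float((d**2).sum())


def _cp(x: np.ndarray, y: np.ndarray) -> float:
    """Sum of mean-deviation cross products of two columns."""
    return float(((x - x.mean()) * (y - y.mean())).sum())


@dataclass
class SSDecomposition:
    """Per-picture split of the picture-score SS into category parts."""

    pictures: tuple[str, ...]
    categories: tuple[str, ...]
    total_ss: np.ndarray                       # SS of each picture-score
    category_ss: np.ndarray                    # (P, C) within-picture SS per category
    cross_products: dict                       # {(pic, cat, cat'): CP sum}
    residual: float = 0.0

    def parts_sum(self, p: int) -> float:
        pic = self.pictures[p]
        cross = sum(
            2.0 * v for (q, _, _), v in self.cross_products.items() if q == pic
        )
        return float(self.category_ss[p].sum() + cross)


def picture_ss_decomposition(t: ScoringTensor) -> SSDecomposition:
    """Split each picture-score SS into category SS and pair cross products.

    For picture p with 0/1 category columns x_{.pc}:
    SS_p = sum_c SS_{pc} + 2 * sum_{c<c'} CP_{p,cc'}.  The residual reports
    the largest absolute discrepancy over pictures (zero up to float error).
    """
    n, np_, nc = t.values.shape
    x = t.values.astype(float)
    total = np.empty(np_)
    cat_ss = np.empty((np_, nc))
    cross: dict = {}
    resid = 0.0
    for p in range(np_):
        block = x[:, p, :]
        total[p] = _ss(block.sum(axis=1))
        for c in range(nc):
            cat_ss[p, c] = _ss(block[:, c])
        parts = cat_ss[p].sum()
        for c in range(nc):
            for c2 in range(c + 1, nc):
                v = _cp(block[:, c], block[:, c2])
                cross[(t.pictures[p], t.categories[c], t.categories[c2])] = v
                parts += 2.0 * v
        resid = max(resid, abs(total[p] - parts))
    return SSDecomposition(
        pictures=t.pictures,
        categories=t.categories,
        total_ss=total,
        category_ss=cat_ss,
        cross_products=cross,
        residual=resid,
    )


@dataclass
class CovarianceSumSummary:
    """Total SS, item SS and the implied pairwise covariance sum (SS form)."""

    mode: str
    n_items: int
    total_ss: float
    item_ss_sum: float
    pairwise_cross_sum: float        # sum over unordered item pairs, SS form
    first_term: float | None = None  # cross-level component, see cross_level_terms

    def check(self) -> float:
        """Residual of SS_T = sum SS_i + 2 * pairwise sum."""
        return abs(self.total_ss - self.item_ss_sum - 2.0 * self.pairwise_cross_sum)


def covariance_sum(m: ItemMatrix) -> CovarianceSumSummary:
    """Total SS, summed item SS, and the pairwise cross-product sum they imply.

    The sum of all unordered pairwise covariances equals half of the total
    test variance minus the item variances; computed in SS form.
    """
    x = np.asarray(m.scores, dtype=float)
    total_ss = _ss(x.sum(axis=1))
    item_ss = sum(_ss(x[:, j]) for j in range(x.shape[1]))
    return CovarianceSumSummary(
        mode=m.mode,
        n_items=m.n_items,
        total_ss=total_ss,
        item_ss_sum=item_ss,
        pairwise_cross_sum=(total_ss - item_ss) / 2.0,
    )


@dataclass
class CrossLevelTerms:
    """The four SS components of the total test score of one tensor.

    total_ss = cell_ss
             + 2 * within_picture_between_category
             + 2 * within_category_between_picture
             + 2 * between_both

    The picture-mode item SS absorbs cell_ss plus the within-picture term;
    the category-mode item SS absorbs cell_ss plus the within-category term.
    The remaining cross products make up each mode's pairwise covariance sum,
    which is how the within-picture category agreement that inflates the
    picture-score variances reappears as category-score covariance.
    """

    total_ss: float
    cell_ss: float
    within_picture_between_category: float
    within_category_between_picture: float
    between_both: float
    picture_summary: CovarianceSumSummary = field(repr=False, default=None)
    category_summary: CovarianceSumSummary = field(repr=False, default=None)

    def residual(self) -> float:
        return abs(
            self.total_ss
            - self.cell_ss
            - 2.0
            * (
                self.within_picture_between_category
                + self.within_category_between_picture
                + self.between_both
            )
        )


def cross_level_terms(t: ScoringTensor) -> CrossLevelTerms:
    """Decompose the total-score SS over picture/category cell pairs.

    Every pair of tensor cells falls in exactly one stratum: same picture
    (different category), same category (different picture), or different in
    both.  Reconciles the picture-mode and category-mode covariance summaries
    against one shared total SS.
    """
    n, np_, nc = t.values.shape
    x = t.values.astype(float).reshape(n, np_ * nc)
    dev = x - x.mean(axis=0)
    cp = dev.T @ dev  # SS-form cross products between all cells

    cell_ss = float(np.trace(cp))
    wp = wc = bb = 0.0
    for a in range(np_ * nc):
        pa, ca = divmod(a, nc)
        for b in range(a + 1, np_ * nc):
            pb, cb = divmod(b, nc)
            if pa == pb:
                wp += cp[a, b]
            elif ca == cb:
                wc += cp[a, b]
            else:
                bb += cp[a, b]

    pic = covariance_sum(to_picture_items(t))
    cat = covariance_sum(to_category_items(t))
    # the first terms distinguishing the two mode-level covariance identities
    pic.first_term = wc
    cat.first_term = wp
    return CrossLevelTerms(
        total_ss=_ss(x.sum(axis=1)),
        cell_ss=cell_ss,
        within_picture_between_category=float(wp),
        within_category_between_picture=float(wc),
        between_both=float(bb),
        picture_summary=pic,
        category_summary=cat,
    )


@dataclass
class AlphaGapReport:
    """alpha(category) - alpha(picture) with the SS terms that drive it."""

    alpha_category: float
    alpha_picture: float
    gap: float
    terms: CrossLevelTerms
    degenerate: bool = False  # pictures are exact copies (gap <= 0 boundary)


def alpha_gap_analysis(t: ScoringTensor) -> AlphaGapReport:
    """Contrast the two mode alphas alongside the shared SS decomposition.

    The within-picture between-category cross-product sum feeds the
    category-mode covariances, so tensors with strong within-story category
    agreement but unstable picture difficulty show a large positive gap.
    When all pictures are identical copies the picture intercorrelations are
    1 and the gap is non-positive; that boundary case is flagged.
    """
    a_cat = alpha(to_category_items(t))
    a_pic = alpha(to_picture_items(t))
    terms = cross_level_terms(t)
    first = t.values[:, 0, :]
    degenerate = all(
        np.array_equal(t.values[:, p, :], first) for p in range(len(t.pictures))
    )
    return AlphaGapReport(
        alpha_category=a_cat,
        alpha_picture=a_pic,
        gap=a_cat - a_pic,
        terms=terms,
        degenerate=degenerate,
    )
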