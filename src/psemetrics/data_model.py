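"""Two-level binary representation of coded Picture Story Exercise data.

A coded PSE is a subjects x pictures x categories tensor of 0/1 scores: for
each story (one subject, one picture) a coder marks which content categories
of the motive scale apply.  The conventional "item" for reliability analysis
is the picture-score (category count within a story); this module also builds
the category-score items (picture count per category) and the fully
dichotomous picture-by-category items, all from the same tensor, so the three
aggregation modes can be compared on identical data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "CodingScheme",
    "WeightingRule",
    "HS_SCHEME",
    "FF_SCHEME",
    "ScoringTensor",
    "ItemMatrix",
    "ScaleScores",
    "derive_weighting",
    "attach_weighting",
    "to_category_items",
    "to_picture_items",
    "to_dichotomous_items",
    "from_dichotomous",
    "scale_scores",
    "worked_example",
    "InvalidSchemeError",
]

AggregationMode = Literal["category", "picture", "dichotomous"]


class InvalidSchemeError(ValueError):
    """A category identifier is unknown to the coding scheme in use."""


@dataclass(frozen=True)
class WeightingRule:
    """Declarative derivation rule for a weighting category (ST or FT).

    The point is awarded per story when the required own-scale categories are
    present and no opposite-scale main category is scored, excepting the
    listed ones.  ``required_any`` and ``required_all`` cannot both be empty.
    """

    required_any: tuple[str, ...] = ()
    required_all: tuple[str, ...] = ()
    opposite_exceptions: tuple[str, ...] = ()


@dataclass(frozen=True)
class CodingScheme:
    """Category definitions for one motive scale of the Heckhausen system."""

    scale_id: str
    main_categories: tuple[str, ...]
    weighting_category: str | None = None
    weighting_rule: WeightingRule | None = None

    def __post_init__(self) -> None:
        cats = list(self.main_categories)
        if self.weighting_category is not None:
            cats.append(self.weighting_category)
        if len(set(cats)) != len(cats):
            raise InvalidSchemeError(
                f"duplicate category identifiers in scheme {self.scale_id!r}"
            )

    @property
    def all_categories(self) -> tuple[str, ...]:
        if self.weighting_category is None:
            return self.main_categories
        return self.main_categories + (self.weighting_category,)


# Heckhausen achievement-motive coding system: five main categories for hope
# of success (HS), six for fear of failure (FF), one weighting category each.
HS_SCHEME = CodingScheme(
    scale_id="HS",
    main_categories=("NS", "IS", "ES", "P", "A+"),
    weighting_category="ST",
    # success theme: NS or ES scored, and no FF main category except A-, EF
    weighting_rule=WeightingRule(
        required_any=("NS", "ES"), opposite_exceptions=("A-", "EF")
    ),
)

FF_SCHEME = CodingScheme(
    scale_id="FF",
    main_categories=("NF", "IF", "EF", "A-", "C", "F"),
    weighting_category="FT",
    # failure theme: NF and F scored, and no HS main category except IS
    weighting_rule=WeightingRule(
        required_all=("NF", "F"), opposite_exceptions=("IS",)
    ),
)

CANONICAL_PICTURES = ("A", "B", "C", "D", "E", "F")


@dataclass
class ScoringTensor:
    """Binary scores x_{jpc} for subject j, picture p, category c (one scale).

    ``values`` has shape (N, P, C).  ``scheme`` is optional: toy or simulated
    data may use free-form category labels without a Heckhausen scheme.
    """

    values: np.ndarray
    pictures: tuple[str, ...]
    categories: tuple[str, ...]
    scale_id: str = "scale"
    scheme: CodingScheme | None = None
    strict: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.pictures = tuple(self.pictures)
        self.categories = tuple(self.categories)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected a 3-d subjects x pictures x categories array, "
                f"got ndim={self.values.ndim}"
            )
        n, p, c = self.values.shape
        if p != len(self.pictures) or c != len(self.categories):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.pictures)} pictures / {len(self.categories)} categories"
            )
        if len(set(self.pictures)) != p or len(set(self.categories)) != c:
            raise ValueError("picture and category labels must be unique")
        if not np.isin(self.values, (0, 1)).all():
            bad = self.values[~np.isin(self.values, (0, 1))][0]
            raise ValueError(f"tensor entries must be 0/1; found {bad}")
        empty = (self.values.sum(axis=2) == 0).all(axis=1)
        if empty.any():
            msg = (
                f"{int(empty.sum())} subject(s) with all-zero codings on "
                f"scale {self.scale_id!r}"
            )
            if self.strict:
                raise ValueError(msg)
            # all-zero stories/subjects are representable but worth flagging:
            # the coding system cannot distinguish a skipped picture from a
            # story with no motive imagery
            warnings.warn(msg, stacklevel=2)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def total_scores(self) -> np.ndarray:
        """Per-subject total score (sum over all pictures and categories)."""
        return self.values.sum(axis=(1, 2))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoringTensor):
            return NotImplemented
        return (
            self.pictures == other.pictures
            and self.categories == other.categories
            and self.scale_id == other.scale_id
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ItemMatrix:
    """Subjects x items score matrix for one aggregation mode."""

    mode: AggregationMode
    items: tuple[str, ...]
    scores: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        self.items = tuple(self.items)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.items):
            raise ValueError("scores must be N x n with one column per item")
        if (self.scores < 0).any():
            raise ValueError("item scores must be non-negative")
        if self.mode == "dichotomous" and not np.isin(self.scores, (0, 1)).all():
            raise ValueError("dichotomous item scores must be 0/1")

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def total_scores(self) -> np.ndarray:
        return self.scores.sum(axis=1)


@dataclass
class ScaleScores:
    """Per-subject totals of both scales and the classic derived scores.

    Net hope NH = HS - FF; resultant achievement motivation = HS + FF.
    """

    hs_total: np.ndarray
    ff_total: np.ndarray

    @property
    def net_hope(self) -> np.ndarray:
        return self.hs_total - self.ff_total

    @property
    def resultant(self) -> np.ndarray:
        return self.hs_total + self.ff_total


def _as_story_vector(
    story: Mapping[str, int] | Sequence[int], scheme: CodingScheme
) -> dict[str, int]:
    if isinstance(story, Mapping):
        unknown = set(story) - set(scheme.main_categories)
        if unknown:
            raise InvalidSchemeError(
                f"unknown categories {sorted(unknown)} for scale {scheme.scale_id}"
            )
        return {c: int(story.get(c, 0)) for c in scheme.main_categories}
    values = list(story)
    if len(values) != len(scheme.main_categories):
        raise InvalidSchemeError(
            f"expected {len(scheme.main_categories)} codings for scale "
            f"{scheme.scale_id}, got {len(values)}"
        )
    return dict(zip(scheme.main_categories, map(int, values)))


def _rule_fires(
    rule: WeightingRule, own: Mapping[str, int], opposite: Mapping[str, int],
    opposite_scheme: CodingScheme,
) -> bool:
    if rule.required_any and not any(own[c] for c in rule.required_any):
        return False
    if rule.required_all and not all(own[c] for c in rule.required_all):
        return False
    for cat in opposite_scheme.main_categories:
        if cat in rule.opposite_exceptions:
            continue
        if opposite[cat]:
            return False
    return True


def derive_weighting(
    hs_story: Mapping[str, int] | Sequence[int],
    ff_story: Mapping[str, int] | Sequence[int],
    *,
    ft_rule: Literal["conjunctive", "disjunctive"] = "conjunctive",
) -> tuple[int, int]:
    """Derive the success-theme (ST) and failure-theme (FT) points for a story.

    ST is awarded when NS or ES is scored and no fear-of-failure main category
    other than A- or EF is present; FT when NF and F are scored and no
    hope-of-success main category other than IS is present.  ``ft_rule``
    switches the NF/F requirement between the conjunctive reading (both, the
    printed rule, default) and a disjunctive one (either).
    """
    hs = _as_story_vector(hs_story, HS_SCHEME)
    ff = _as_story_vector(ff_story, FF_SCHEME)
    st_rule = HS_SCHEME.weighting_rule
    ft = FF_SCHEME.weighting_rule
    assert st_rule is not None and ft is not None
    if ft_rule == "disjunctive":
        ft = WeightingRule(
            required_any=ft.required_all, opposite_exceptions=ft.opposite_exceptions
        )
    elif ft_rule != "conjunctive":
        raise ValueError(f"ft_rule must be conjunctive|disjunctive, got {ft_rule!r}")
    st = int(_rule_fires(st_rule, hs, ff, FF_SCHEME))
    ftv = int(_rule_fires(ft, ff, hs, HS_SCHEME))
    return st, ftv


def attach_weighting(
    hs: ScoringTensor,
    ff: ScoringTensor,
    *,
    ft_rule: Literal["conjunctive", "disjunctive"] = "conjunctive",
) -> tuple[ScoringTensor, ScoringTensor]:
    """Append the derived ST / FT columns to paired HS and FF tensors.

    The weighting categories depend on *both* scales' codings of the same
    story, so derivation is a paired operation.  Input tensors must hold the
    main categories only, in scheme order, for the same subjects and pictures.
    """
    for t, scheme in ((hs, HS_SCHEME), (ff, FF_SCHEME)):
        if t.categories != scheme.main_categories:
            raise InvalidSchemeError(
                f"{scheme.scale_id} tensor must carry exactly the main "
                f"categories {scheme.main_categories}, got {t.categories}"
            )
    if hs.n_subjects != ff.n_subjects or hs.pictures != ff.pictures:
        raise ValueError("HS and FF tensors must share subjects and pictures")

    n, p = hs.n_subjects, len(hs.pictures)
    st = np.zeros((n, p, 1), dtype=np.int64)
    ft = np.zeros((n, p, 1), dtype=np.int64)
    for j in range(n):
        for k in range(p):
            s, f = derive_weighting(hs.values[j, k], ff.values[j, k], ft_rule=ft_rule)
            st[j, k, 0] = s
            ft[j, k, 0] = f
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hs_w = ScoringTensor(
            np.concatenate([hs.values, st], axis=2),
            hs.pictures,
            HS_SCHEME.all_categories,
            scale_id="HS",
            scheme=HS_SCHEME,
        )
        ff_w = ScoringTensor(
            np.concatenate([ff.values, ft], axis=2),
            ff.pictures,
            FF_SCHEME.all_categories,
            scale_id="FF",
            scheme=FF_SCHEME,
        )
    return hs_w, ff_w


def _maybe_drop_weighting(t: ScoringTensor, include_weighting: bool) -> ScoringTensor:
    if include_weighting:
        return t
    scheme = t.scheme
    if scheme is None or scheme.weighting_category not in t.categories:
        return t
    keep = [i for i, c in enumerate(t.categories) if c != scheme.weighting_category]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ScoringTensor(
            t.values[:, :, keep],
            t.pictures,
            tuple(t.categories[i] for i in keep),
            scale_id=t.scale_id,
            scheme=scheme,
        )


def to_category_items(t: ScoringTensor, include_weighting: bool = True) -> ItemMatrix:
    """Category-score items: entry (j, c) counts pictures where c was coded."""
    t = _maybe_drop_weighting(t, include_weighting)
    return ItemMatrix(
        mode="category",
        items=t.categories,
        scores=t.values.sum(axis=1),
        provenance={"scale_id": t.scale_id, "include_weighting": include_weighting},
    )


def to_picture_items(t: ScoringTensor, include_weighting: bool = True) -> ItemMatrix:
    """Picture-score items: entry (j, p) counts categories coded in story p."""
    t = _maybe_drop_weighting(t, include_weighting)
    return ItemMatrix(
        mode="picture",
        items=t.pictures,
        scores=t.values.sum(axis=2),
        provenance={"scale_id": t.scale_id, "include_weighting": include_weighting},
    )


def to_dichotomous_items(
    t: ScoringTensor, include_weighting: bool = True
) -> ItemMatrix:
    """0/1 items, one per (picture, category) cell, picture-major order."""
    t = _maybe_drop_weighting(t, include_weighting)
    n, p, c = t.values.shape
    labels = tuple(f"{pic}_{cat}" for pic in t.pictures for cat in t.categories)
    return ItemMatrix(
        mode="dichotomous",
        items=labels,
        scores=t.values.reshape(n, p * c),
        provenance={
            "scale_id": t.scale_id,
            "include_weighting": include_weighting,
            "pictures": t.pictures,
            "categories": t.categories,
        },
    )


def from_dichotomous(m: ItemMatrix) -> ScoringTensor:
    """Rebuild the scoring tensor from its dichotomous item matrix."""
    if m.mode != "dichotomous":
        raise ValueError("round trip requires a dichotomous item matrix")
    pictures = m.provenance.get("pictures")
    categories = m.provenance.get("categories")
    if pictures is None or categories is None:
        # recover labels from the PICTURE_CATEGORY column names
        pairs = [lab.split("_", 1) for lab in m.items]
        pictures = tuple(dict.fromkeys(p for p, _ in pairs))
        categories = tuple(dict.fromkeys(c for _, c in pairs))
    n = m.n_subjects
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ScoringTensor(
            m.scores.reshape(n, len(pictures), len(categories)),
            tuple(pictures),
            tuple(categories),
            scale_id=m.provenance.get("scale_id", "scale"),
        )


def scale_scores(hs: ScoringTensor, ff: ScoringTensor) -> ScaleScores:
    """Per-subject HS and FF totals plus net hope and resultant motivation."""
    if hs.n_subjects != ff.n_subjects:
        raise ValueError(
            f"subject counts differ: HS has {hs.n_subjects}, FF has {ff.n_subjects}"
        )
    return ScaleScores(hs_total=hs.total_scores(), ff_total=ff.total_scores())


#: the printed 7-subject, 3-picture, 3-category demonstration tensor;
#: rows are subjects, blocks are pictures A..C, columns categories Cat1..Cat3
_WORKED_EXAMPLE = np.array(
    [
        # picture A     picture B     picture C
        [[1, 1, 1], [1, 1, 1], [1, 1, 1]],
        [[0, 1, 1], [1, 0, 1], [1, 1, 0]],
        [[0, 0, 1], [1, 0, 0], [0, 1, 0]],
        [[0, 0, 0], [1, 1, 1], [1, 1, 1]],
        [[1, 1, 1], [0, 0, 0], [1, 1, 1]],
        [[1, 1, 1], [1, 1, 1], [0, 0, 0]],
        [[1, 1, 0], [1, 0, 1], [1, 1, 1]],
    ],
    dtype=np.int64,
)


def worked_example() -> ScoringTensor:
    """The canonical 7 x 3 x 3 demonstration tensor.

    Seven subjects, pictures A-C, categories Cat1-Cat3.  Constructed so that
    category-scores intercorrelate highly while picture-scores intercorrelate
    near zero or negatively, despite identical subject totals — the minimal
    data set exhibiting the category-mode reliability advantage.
    """
    return ScoringTensor(
        _WORKED_EXAMPLE.copy(),
        pictures=("A", "B", "C"),
        categories=("Cat1", "Cat2", "Cat3"),
        scale_id="demo",
    )
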