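"""Reader-error summarization and case-difficulty labelling.

A panel of readers rates every case on the 5-point RANZCR suspicion scale
(1 normal ... 5 definitely malignant) and may annotate a suspicious location.
Ratings of 3 and above are positive calls.  Per case and per error basis the
proportion of readers committing the error is the case's difficulty score:

* ``FP``       — positive call on a cancer-free case;
* ``FN``       — negative call on a cancer case (case-based difficulty);
* ``location`` — failure to correctly localize a cancer (lesion-based
  difficulty): a localization is correct when the annotated point lies
  within ``radius`` pixels (default 250, inclusive) of a true lesion in the
  same view.

Cases are then ranked by proportion and split into three near-equal tertiles
(easy / median / difficult); the median tertile is excluded from modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IncompletePanelError, InputError

__all__ = [
    "ErrorSummary",
    "DifficultyLabel",
    "rating_to_binary",
    "localization_correct",
    "summarize_errors",
    "tertile_split",
]

BASES = ("FP", "FN", "location")
TERTILES = ("easy", "median", "difficult")


@dataclass(frozen=True)
class ErrorSummary:
    case_id: str
    basis: str
    n_readers: int
    n_errors: int

    @property
    def proportion(self) -> float:
        return self.n_errors / self.n_readers


@dataclass(frozen=True)
class DifficultyLabel:
    case_id: str
    basis: str
    tertile: str  # easy | median | difficult


def rating_to_binary(rating: int) -> bool:
    """True (positive call) iff rating >= 3 on the 1-5 RANZCR scale."""
    if rating not in (1, 2, 3, 4, 5):
        raise InputError(f"rating must be in 1..5, got {rating!r}")
    return rating >= 3


def localization_correct(annotation, lesions, radius: float = 250.0) -> bool:
    """Whether an annotated point correctly localizes any lesion.

    ``annotation`` is ``(view, row, col)``; ``lesions`` an iterable of the
    same triples.  Distance is Euclidean, compared only within the same
    view, and the boundary is inclusive (distance == radius is correct).
    """
    view, r, c = annotation
    if view is None or (isinstance(view, float) and math.isnan(view)) or view == "":
        raise InputError("annotation must carry a view tag")
    lesions = list(lesions)
    if not lesions:
        raise InputError("localization_correct requires at least one lesion")
    for lv, lr, lc in lesions:
        if lv != view:
            continue
        if math.hypot(float(r) - float(lr), float(c) - float(lc)) <= radius:
            return True
    return False


def _highest_rated(responses: pd.DataFrame) -> pd.DataFrame:
    """Keep each reader's highest-rated annotation per case (stable ties)."""
    idx = (
        responses.reset_index(drop=True)
        .groupby(["reader_id", "case_id"], sort=False)["rating"]
        .idxmax()
    )
    return responses.reset_index(drop=True).loc[idx]


def _check_complete(responses: pd.DataFrame, case_ids) -> None:
    readers = responses["reader_id"].unique()
    have = set(zip(responses["reader_id"], responses["case_id"]))
    missing = [(r, c) for r in readers for c in case_ids if (r, c) not in have]
    if missing:
        raise IncompletePanelError(missing)


def summarize_errors(
    responses: pd.DataFrame,
    truth: pd.DataFrame,
    basis: str,
    radius: float = 250.0,
    location_denominator: str = "all",
) -> list[ErrorSummary]:
    """Per-case error proportions for one basis.

    Parameters
    ----------
    responses
        Columns ``reader_id, case_id, rating, view, x, y`` (view/x/y may be
        blank when no annotation was made; x = column, y = row).  Multiple
        annotations per reader and case are reduced to the highest-rated one.
    truth
        Columns ``case_id, cancer, lesion_view, lesion_x, lesion_y``; cancer
        cases may span several rows (one per lesion).
    basis
        ``FP`` (cancer-free cases only), ``FN`` or ``location`` (cancer only).
    location_denominator
        ``all`` counts every reader in the denominator (a missed cancer can
        never be correctly localized); ``positives`` counts only readers who
        called the case positive.
    """
    if basis not in BASES:
        raise InputError(f"basis must be one of {BASES}")
    if location_denominator not in ("all", "positives"):
        raise InputError("location_denominator must be 'all' or 'positives'")
    for col in ("reader_id", "case_id", "rating"):
        if col not in responses.columns:
            raise InputError(f"responses missing column {col!r}")

    cancer_by_case = truth.groupby("case_id")["cancer"].first().astype(bool)
    wanted_cancer = basis != "FP"
    case_ids = [cid for cid, is_ca in cancer_by_case.items() if is_ca == wanted_cancer]
    if not case_ids:
        raise InputError(f"no {'cancer' if wanted_cancer else 'cancer-free'} cases for basis {basis}")

    resp = responses[responses["case_id"].isin(case_ids)]
    _check_complete(resp, case_ids)
    resp = _highest_rated(resp)
    resp["rating"].map(rating_to_binary)  # validates range

    lesions_by_case: dict[str, list] = {}
    if wanted_cancer:
        for cid in case_ids:
            rows = truth[(truth["case_id"] == cid) & truth["lesion_view"].notna()]
            lesions_by_case[cid] = [
                (r.lesion_view, float(r.lesion_y), float(r.lesion_x)) for r in rows.itertuples()
            ]
            if not lesions_by_case[cid]:
                raise InputError(f"cancer case {cid} has no lesion coordinates")

    summaries = []
    for cid in case_ids:
        rows = resp[resp["case_id"] == cid]
        positive = rows["rating"].map(rating_to_binary)
        if basis == "FP":
            n, k = len(rows), int(positive.sum())
        elif basis == "FN":
            n, k = len(rows), int((~positive).sum())
        else:
            lesions = lesions_by_case[cid]
            errs = 0
            n = 0
            for row, pos in zip(rows.itertuples(), positive):
                has_annot = (
                    pos
                    and isinstance(getattr(row, "view", None), str)
                    and row.view != ""
                    and pd.notna(row.x)
                    and pd.notna(row.y)
                )
                if location_denominator == "positives" and not pos:
                    continue
                n += 1
                if not has_annot:
                    errs += 1  # missed case (or unannotated positive) cannot localize
                elif not localization_correct((row.view, float(row.y), float(row.x)), lesions, radius):
                    errs += 1
            if n == 0:
                continue
            k = errs
        summaries.append(ErrorSummary(cid, basis, n, k))
    return summaries


def tertile_split(summaries: list[ErrorSummary]) -> list[DifficultyLabel]:
    """Rank cases by error proportion into easy / median / difficult.

    Sort ascending by proportion with case_id as the deterministic
    tie-break; tertile sizes differ by at most one (the easy, then the
    difficult group absorb the remainder).
    """
    if len(summaries) < 3:
        raise InputError("tertile_split needs at least 3 cases")
    bases = {s.basis for s in summaries}
    if len(bases) != 1:
        raise InputError("tertile_split expects summaries from a single basis")
    basis = bases.pop()
    order = sorted(summaries, key=lambda s: (s.proportion, s.case_id))
    n = len(order)
    base, rem = divmod(n, 3)
    n_easy = base + (1 if rem >= 1 else 0)
    n_diff = base + (1 if rem >= 2 else 0)
    labels = []
    for i, s in enumerate(order):
        if i < n_easy:
            tert = "easy"
        elif i >= n - n_diff:
            tert = "difficult"
        else:
            tert = "median"
        labels.append(DifficultyLabel(s.case_id, basis, tert))
    return labels


def labels_frame(labels: list[DifficultyLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {"case_id": [l.case_id for l in labels],
         "basis": [l.basis for l in labels],
         "tertile": [l.tertile for l in labels]}
    )


def modelling_labels(labels: list[DifficultyLabel]) -> pd.Series:
    """Binary target (difficult=1, easy=0) with the median tertile dropped."""
    keep = [l for l in labels if l.tertile != "median"]
    s = pd.Series(
        {l.case_id: 1 if l.tertile == "difficult" else 0 for l in keep}, dtype=int
    )
    s.index.name = "case_id"
    return s
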