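"""Screening-campaign statistics.

Confusion counts against labeled actives/inactives/decoys, ROC curves and
AUC over per-molecule scores, enrichment factors, and property-matched
decoy selection in the DUD-E style (match each decoy to some active within
per-property tolerances over molecular weight, H-bond donor/acceptor
counts, rotatable bonds, formal charge and apolar-atom fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DegenerateInputError, LabelingError
from .screening import NO_MATCH_SCORE, ScreenReport
from .structio import FeaturePoint

LABELS = ("active", "inactive", "decoy")


@dataclass(frozen=True)
class LibraryEntry:
    molecule_id: str
    label: str
    properties: dict[str, float]
    conformers: tuple[tuple[FeaturePoint, ...], ...]

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class LabeledLibrary:
    entries: tuple[LibraryEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.molecule_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("molecule ids must be unique")

    def labels(self) -> dict[str, str]:
        return {e.molecule_id: e.label for e in self.entries}

    def as_screen_input(self) -> list[tuple[str, list[tuple[FeaturePoint, ...]]]]:
        return [(e.molecule_id, list(e.conformers)) for e in self.entries]

    def subset(self, label: str) -> tuple[LibraryEntry, ...]:
        return tuple(e for e in self.entries if e.label == label)


@dataclass(frozen=True)
class ConfusionReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        n = self.tp + self.fn
        return self.tp / n if n else None

    @property
    def specificity(self) -> float | None:
        n = self.tn + self.fp
        return self.tn / n if n else None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def evaluate_screen(report: ScreenReport, labels: dict[str, str]) -> ConfusionReport:
    """Confusion counts of a screen against activity labels.

    Actives are the positive class; inactives and decoys together form the
    negative class.  Every screened molecule must carry a label.
    """
    missing = [r.molecule_id for r in report.results if r.molecule_id not in labels]
    if missing:
        raise LabelingError(f"unlabeled molecules: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    tp = fp = tn = fn = 0
    for r in report.results:
        active = labels[r.molecule_id] == "active"
        if r.hit:
            tp += active
            fp += not active
        else:
            fn += active
            tn += not active
    return ConfusionReport(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class ROCReport:
    points: tuple[tuple[float, float], ...]  # (FPR, TPR)
    auc: float
    confusion: ConfusionReport | None
    enrichment_factor_at_fraction: dict[float, float]


def roc_curve(
    scores: dict[str, float],
    labels: dict[str, str],
    confusion: ConfusionReport | None = None,
    ef_fractions: tuple[float, ...] = (0.01, 0.05, 0.1),
) -> ROCReport:
    """ROC/AUC over per-molecule scores (no-match = sentinel below all).

    The threshold sweep runs over distinct score values (ties share a
    step); AUC is the trapezoid area.  EF(f) is the precision among the
    top-f fraction divided by the active base rate.
    """
    ids = sorted(scores)
    missing = [i for i in ids if i not in labels]
    if missing:
        raise LabelingError(f"unlabeled molecules: {missing[:10]}")
    y = np.array([labels[i] == "active" for i in ids], dtype=int)
    s = np.array([scores[i] for i in ids], dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateInputError("need at least one active and one non-active")
    # map the no-match sentinel to a finite value below all real scores so
    # the trapezoid arithmetic stays finite
    finite = s[np.isfinite(s)]
    floor = (finite.min() - 1.0) if finite.size else 0.0
    s = np.where(np.isfinite(s), s, floor)

    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    area = float(_sk_auc(fpr, tpr))

    base_rate = y.mean()
    order = np.lexsort((np.array(ids), -s))  # score desc, id asc for ties
    ef = {}
    for f in ef_fractions:
        k = max(1, int(math.floor(f * len(ids))))
        precision = y[order[:k]].mean()
        ef[f] = float(precision / base_rate)
    return ROCReport(
        points=tuple((float(a), float(b)) for a, b in zip(fpr, tpr)),
        auc=area,
        confusion=confusion,
        enrichment_factor_at_fraction=ef,
    )


# ---------------------------------------------------------------------------
# Property-matched decoy selection
# ---------------------------------------------------------------------------

#: Per-property matching tolerances (DUD-E-style sextet).
DEFAULT_DECOY_TOLERANCES: dict[str, float] = {
    "mw": 25.0,
    "hba_count": 1.0,
    "hbd_count": 1.0,
    "rotatable_bonds": 1.0,
    "formal_charge": 0.0,
    "apolar_fraction": 0.1,
}


@dataclass(frozen=True)
class DecoySelection:
    selected: tuple[str, ...]
    matched_active: dict[str, str]  # decoy id -> the active it matched
    requested: int
    shortfall: int

    @property
    def fulfilled(self) -> bool:
        return self.shortfall == 0


def pick_decoys(
    actives: list[dict],
    pool: list[dict],
    tolerances: dict[str, float] | None = None,
    ratio: int = 50,
    seed: int = 0,
) -> DecoySelection:
    """Select property-matched decoys from a candidate pool.

    ``actives`` and ``pool`` are lists of ``{"id": ..., <property>: value}``
    records carrying every property named in ``tolerances``.  A candidate
    is eligible when all its properties lie within tolerance of some single
    active.  Selection is deterministic: eligible candidates in id order;
    when more are eligible than ``ratio * n_actives``, a seeded choice
    without replacement is drawn.  An infeasible request yields an explicit
    shortfall report, never silent padding.
    """
    tol = dict(DEFAULT_DECOY_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    props = sorted(tol)
    for rec in list(actives) + list(pool):
        absent = [p for p in props if p not in rec]
        if absent:
            raise LabelingError(f"record {rec.get('id')!r} missing properties {absent}")

    eligible: list[tuple[str, str]] = []
    for cand in sorted(pool, key=lambda r: str(r["id"])):
        for act in actives:
            if all(abs(cand[p] - act[p]) <= tol[p] for p in props):
                eligible.append((str(cand["id"]), str(act["id"])))
                break
    requested = ratio * len(actives)
    if len(eligible) > requested:
        rng = np.random.Generator(np.random.Philox(seed))
        idx = rng.choice(len(eligible), size=requested, replace=False)
        eligible = [eligible[i] for i in sorted(idx)]
    selected = tuple(c for c, _ in eligible)
    return DecoySelection(
        selected=selected,
        matched_active=dict(eligible),
        requested=requested,
        shortfall=max(0, requested - len(selected)),
    )
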