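"""Significance gating, replication across cohorts, and robustness summaries.

An effect (independent or moderation) within one cohort only counts when it
is significant in both the least-squares and the robust fit (the dual gate).
It is only reported as a finding when the dual-gated effect appears in both
cohorts with the same coefficient sign (the replication gate). Robustness of
a proxy is the percentage of the brain-cognition model grid in which its
effect replicates, and effect size is the mean R-squared increment over the
significant cells of both cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .regression import CompleteReserveResults

__all__ = [
    "EffectRecord",
    "RobustnessSummary",
    "dual_gate",
    "replication_gate",
    "classify_moderation",
    "bonferroni_alpha",
    "comparison_budget",
    "robustness_summary",
    "records_from_result",
]

INDEPENDENT = "independent"
MODERATION = "moderation"


@dataclass(frozen=True)
class EffectRecord:
    """One proxy effect in one cell of one cohort, before gating."""

    proxy: str
    members: frozenset
    dataset: str
    brain: str
    cognition: str
    kind: str                      # "independent" (step 2) or "moderation" (step 3)
    delta_r2: float
    ols_p: float
    robust_p: float
    sign: int
    n: int

    def __post_init__(self) -> None:
        if self.kind not in (INDEPENDENT, MODERATION):
            raise ValueError(f"unknown effect kind {self.kind!r}")

    @property
    def cell(self) -> tuple[str, str]:
        return (self.brain, self.cognition)


@dataclass(frozen=True)
class RobustnessSummary:
    """Replication robustness and mean effect size for one proxy."""

    proxy: str
    kind: str
    n_models: int
    n_replicated: int
    robustness_pct: float
    mean_delta_r2_significant: float   # mean over significant cells, both cohorts
    mean_delta_r2_all: float           # mean over every cell, both cohorts


def _check_p(p: float, label: str) -> None:
    if not (0.0 < p <= 1.0):
        raise ValueError(f"{label} must lie in (0, 1], got {p!r}")


def dual_gate(ols_p: float, robust_p: float, alpha: float = 0.05) -> bool:
    """True iff the effect is significant under both estimators."""
    _check_p(ols_p, "OLS p-value")
    _check_p(robust_p, "robust p-value")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return bool(ols_p < alpha and robust_p < alpha)


def replication_gate(a: EffectRecord, b: EffectRecord, alpha: float = 0.05,
                     require_sign_agreement: bool = True) -> bool:
    """True iff the same effect passes the dual gate in both cohorts.

    The two records must describe the same proxy (by member set), the same
    brain-cognition cell and the same effect kind in two different cohorts.
    By default the coefficient signs must also agree: a pair significant in
    opposite directions is not a replication.
    """
    if a.dataset == b.dataset:
        raise ValueError("replication requires records from different cohorts")
    if a.members != b.members:
        raise ValueError(f"proxy mismatch: {a.proxy!r} vs {b.proxy!r}")
    if a.cell != b.cell or a.kind != b.kind:
        raise ValueError(
            f"cell/kind mismatch: {a.cell + (a.kind,)} vs {b.cell + (b.kind,)}"
        )
    ok = dual_gate(a.ols_p, a.robust_p, alpha) and dual_gate(b.ols_p, b.robust_p, alpha)
    if ok and require_sign_agreement:
        ok = a.sign == b.sign and a.sign != 0
    return ok


def classify_moderation(sign: int | float) -> str:
    """Interpret a moderation-coefficient sign against the reserve hypothesis.

    A negative interaction (weaker brain-cognition coupling at higher proxy
    values) is consistent with the cognitive-reserve hypothesis; a positive
    one contradicts it.
    """
    if sign < 0:
        return "consistent with CR"
    if sign > 0:
        return "contradicts CR"
    raise ValueError("moderation sign of exactly zero is undefined")


def bonferroni_alpha(alpha: float, m: int, ndigits: int | None = None) -> float:
    """Per-comparison alpha under a Bonferroni correction for m comparisons.

    Reports round to 4 decimals (pass ``ndigits=4``); the unrounded value is
    returned by default so the threshold itself stays strictly monotone in m.
    """
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    adj = alpha / m
    return round(adj, ndigits) if ndigits is not None else adj


def comparison_budget(n_proxies: int, n_models: int) -> int:
    """Total comparisons across all proxies and brain-cognition models."""
    if n_proxies < 1 or n_models < 1:
        raise ValueError("counts must be >= 1")
    return int(n_proxies) * int(n_models)


def records_from_result(result: CompleteReserveResults,
                        members: Iterable[str] | None = None) -> list[EffectRecord]:
    """Extract the independent and moderation effect records from one fit."""
    members = frozenset(members) if members is not None else frozenset(
        result.proxy.split("+"))
    common = dict(proxy=result.proxy, members=members,
                  dataset=result.spec.dataset, brain=result.spec.brain,
                  cognition=result.spec.cognition, n=result.n)
    rp2 = result.robust_p_step2 if 2 in result.robust_fits else math.nan
    rp3 = result.robust_p_step3 if 3 in result.robust_fits else math.nan
    return [
        EffectRecord(kind=INDEPENDENT, delta_r2=result.delta_r2_step2,
                     ols_p=result.p_added_step2, robust_p=rp2,
                     sign=result.proxy_sign, **common),
        EffectRecord(kind=MODERATION, delta_r2=result.delta_r2_step3,
                     ols_p=result.p_added_step3, robust_p=rp3,
                     sign=result.interaction_sign, **common),
    ]


def robustness_summary(records: Sequence[EffectRecord], alpha: float = 0.05,
                       require_sign_agreement: bool = True) -> RobustnessSummary:
    """Summarize replication robustness for one proxy and one effect kind.

    `records` must hold, for a single proxy and kind, one record per
    brain-cognition cell in each of exactly two cohorts; a missing cell in
    either cohort is an error listing the gaps. The robustness percentage is
    100 * (replicated cells) / (cells), to two decimals; the significant-cell
    mean R-squared increment averages the increments of both cohorts over
    replicated cells only (NaN when nothing replicates).
    """
    if not records:
        raise ValueError("no effect records supplied")
    kinds = {r.kind for r in records}
    member_sets = {r.members for r in records}
    if len(kinds) != 1 or len(member_sets) != 1:
        raise ValueError("records must cover exactly one proxy and one effect kind")
    datasets = sorted({r.dataset for r in records})
    if len(datasets) != 2:
        raise ValueError(f"expected records from exactly 2 cohorts, got {datasets}")
    cells = sorted({r.cell for r in records})
    by_key = {(r.dataset, r.cell): r for r in records}
    missing = [(d, c) for d in datasets for c in cells if (d, c) not in by_key]
    if missing:
        raise ValueError(f"incomplete model grid; missing cells: {missing}")

    n_models = len(cells)
    replicated = []
    for cell in cells:
        a, b = by_key[(datasets[0], cell)], by_key[(datasets[1], cell)]
        if replication_gate(a, b, alpha, require_sign_agreement):
            replicated.append(cell)

    sig_values = [by_key[(d, cell)].delta_r2
                  for cell in replicated for d in datasets]
    all_values = [r.delta_r2 for r in records]
    rec = records[0]
    return RobustnessSummary(
        proxy=rec.proxy,
        kind=rec.kind,
        n_models=n_models,
        n_replicated=len(replicated),
        robustness_pct=round(100.0 * len(replicated) / n_models, 2),
        mean_delta_r2_significant=(float(np.mean(sig_values)) if sig_values
                                   else math.nan),
        mean_delta_r2_all=float(np.mean(all_values)),
    )
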