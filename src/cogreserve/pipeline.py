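"""End-to-end orchestration: prepare cohorts, run the proxy-by-model grid in
each cohort, and gate/summarize effects across cohorts.

`prepare_cohort` turns a raw cohort table into analysis variables (Winsorized
and standardized proxies, composite proxy columns, Winsorized brain and
cognition variables). `run_dataset_grid` fits the three-step hierarchical
model with its robust re-fit for every (proxy, brain, cognition) cell of one
cohort. `run_study` does this for two cohorts and applies the dual and
replication gates to produce per-proxy robustness summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import aggregation as agg
from .composites import ProxyDefinition, build_composite, full_proxy_set
from .preprocess import (VariableVector, WinsorSpec, mad_winsorize, standardize,
                         z_winsorize)
from .regression import ModelSpec, build_model_grid, fit_hierarchical

__all__ = [
    "prepare_cohort",
    "run_dataset_grid",
    "run_study",
    "StudyResults",
    "records_from_effects",
]

EFFECT_COLUMNS = ["dataset", "proxy", "members", "brain", "cognition", "kind",
                  "delta_r2", "ols_p", "robust_p", "sign", "n"]


def prepare_cohort(df: pd.DataFrame, proxy_names: Sequence[str],
                   brain_names: Sequence[str], cognition_names: Sequence[str],
                   winsor: WinsorSpec | None = None,
                   ) -> tuple[pd.DataFrame, list[ProxyDefinition]]:
    """Build the analysis table: processed proxies, composites, brain, cognition.

    Individual proxies are Winsorized (median +/- 3 scaled MADs) then
    standardized. Composite proxies are the mean of their members'
    standardized values, then Winsorized. Brain variables are standardized
    and clamped at |z| = 3; cognition variables are Winsorized then
    standardized. Returns the augmented table and the full proxy set
    (2^k - 1 definitions) whose names are columns of the table.
    """
    winsor = winsor or WinsorSpec()
    out = df.copy()
    if "age_z" not in out.columns:
        if "age" not in out.columns:
            raise ValueError("cohort table needs an 'age' or 'age_z' column")
        age = out["age"]
        out["age_z"] = (age - age.mean()) / age.std(ddof=1)

    processed: dict[str, VariableVector] = {}
    for name in proxy_names:
        v = VariableVector.from_series(out[name])
        v = standardize(mad_winsorize(v, winsor))
        processed[name] = v
        out[name] = v.values

    proxies = full_proxy_set(proxy_names)
    composite_cols = {}
    for definition in proxies:
        if not definition.is_composite:
            continue
        comp = build_composite([processed[m] for m in definition.members])
        comp = mad_winsorize(comp, winsor)
        composite_cols[definition.name] = comp.values
    if composite_cols:
        out = pd.concat([out, pd.DataFrame(composite_cols, index=out.index)],
                        axis=1)

    for name in brain_names:
        v = standardize(VariableVector.from_series(out[name]))
        out[name] = z_winsorize(v, threshold=winsor.k).values

    for name in cognition_names:
        v = VariableVector.from_series(out[name])
        out[name] = standardize(mad_winsorize(v, winsor)).values

    return out, proxies


def run_dataset_grid(df: pd.DataFrame, dataset: str,
                     proxies: Sequence[ProxyDefinition],
                     brain_names: Sequence[str], cognition_names: Sequence[str],
                     robust: bool = True, **fit_kwargs) -> pd.DataFrame:
    """Fit every (proxy, brain, cognition) cell of one cohort.

    Returns a long-format table with one row per cell and effect kind
    (independent / moderation), carrying the R-squared increment, OLS and
    robust p-values, coefficient sign and complete-case n.
    """
    specs = build_model_grid(brain_names, cognition_names, dataset=dataset)
    rows = []
    for spec in specs:
        for definition in proxies:
            result = fit_hierarchical(df, spec, definition.name,
                                      robust=robust, **fit_kwargs)
            for rec in agg.records_from_result(result, definition.members):
                rows.append({
                    "dataset": rec.dataset, "proxy": rec.proxy,
                    "members": "+".join(sorted(rec.members)),
                    "brain": rec.brain, "cognition": rec.cognition,
                    "kind": rec.kind, "delta_r2": rec.delta_r2,
                    "ols_p": rec.ols_p, "robust_p": rec.robust_p,
                    "sign": rec.sign, "n": rec.n,
                })
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)


def records_from_effects(effects: pd.DataFrame) -> list[agg.EffectRecord]:
    """Rehydrate EffectRecords from a long-format effects table."""
    records = []
    for row in effects.itertuples(index=False):
        records.append(agg.EffectRecord(
            proxy=row.proxy, members=frozenset(row.members.split("+")),
            dataset=row.dataset, brain=row.brain, cognition=row.cognition,
            kind=row.kind, delta_r2=float(row.delta_r2),
            ols_p=float(row.ols_p), robust_p=float(row.robust_p),
            sign=int(row.sign), n=int(row.n),
        ))
    return records


@dataclass
class StudyResults:
    """Joint results of a two-cohort proxy-validation study."""

    effects: pd.DataFrame        # long format, both cohorts
    summaries: pd.DataFrame      # one row per shared proxy x effect kind
    alpha: float
    datasets: tuple[str, str]

    def to_csv(self, out_dir: str | Path) -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        eff_path = out / "effects.csv"
        sum_path = out / "summary.csv"
        self.effects.to_csv(eff_path, index=False)
        self.summaries.to_csv(sum_path, index=False)
        return eff_path, sum_path

    def plot_robustness(self, kind: str = agg.INDEPENDENT, ax=None):
        from .plotting import plot_robustness
        return plot_robustness(self.summaries, kind=kind, ax=ax)


def summarize_effects(effects: pd.DataFrame, alpha: float = 0.05,
                      require_sign_agreement: bool = True) -> pd.DataFrame:
    """Replication summaries for every proxy present in both cohorts."""
    datasets = sorted(effects["dataset"].unique())
    if len(datasets) != 2:
        raise ValueError(f"expected effects from exactly 2 cohorts, got {datasets}")
    records = records_from_effects(effects)
    by_proxy_kind: dict[tuple[frozenset, str], list[agg.EffectRecord]] = {}
    for rec in records:
        by_proxy_kind.setdefault((rec.members, rec.kind), []).append(rec)
    rows = []
    for (members, kind), recs in sorted(
            by_proxy_kind.items(), key=lambda kv: (kv[0][1], kv[1][0].proxy)):
        if {r.dataset for r in recs} != set(datasets):
            continue  # proxy not measurable in both cohorts
        s = agg.robustness_summary(recs, alpha=alpha,
                                   require_sign_agreement=require_sign_agreement)
        rows.append({
            "proxy": s.proxy, "kind": s.kind, "n_models": s.n_models,
            "n_replicated": s.n_replicated, "robustness_pct": s.robustness_pct,
            "mean_delta_r2_significant": s.mean_delta_r2_significant,
            "mean_delta_r2_all": s.mean_delta_r2_all,
        })
    return pd.DataFrame(rows)


def run_study(cohort_a: pd.DataFrame, cohort_b: pd.DataFrame, *,
              dataset_a: str, dataset_b: str,
              proxies_a: Sequence[str], proxies_b: Sequence[str],
              brain_names: Sequence[str], cognition_names: Sequence[str],
              alpha: float = 0.05, require_sign_agreement: bool = True,
              prepare: bool = True, winsor: WinsorSpec | None = None,
              **fit_kwargs) -> StudyResults:
    """Run the full validation study over two cohorts.

    Fits every proxy (individual and composite) in every brain-cognition
    model of each cohort, with OLS and robust inference, then gates effects
    for dual significance, cross-cohort replication and sign agreement, and
    summarizes per-proxy robustness for the proxies shared by both cohorts.
    """
    if dataset_a == dataset_b:
        raise ValueError("the two cohorts need distinct dataset labels")
    frames = []
    for df, dataset, proxy_names in ((cohort_a, dataset_a, proxies_a),
                                     (cohort_b, dataset_b, proxies_b)):
        if prepare:
            df, proxy_defs = prepare_cohort(df, proxy_names, brain_names,
                                            cognition_names, winsor=winsor)
        else:
            proxy_defs = full_proxy_set(proxy_names)
        frames.append(run_dataset_grid(df, dataset, proxy_defs, brain_names,
                                       cognition_names, **fit_kwargs))
    effects = pd.concat(frames, ignore_index=True)
    summaries = summarize_effects(effects, alpha=alpha,
                                  require_sign_agreement=require_sign_agreement)
    return StudyResults(effects=effects, summaries=summaries, alpha=alpha,
                        datasets=(dataset_a, dataset_b))
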