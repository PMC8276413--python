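"""Variable-level preprocessing: z-scoring, robust Winsorization, reverse
coding, and the episodic-memory / global-cognition composites.

Every operation consumes and returns a :class:`VariableVector`, an immutable
per-subject value vector that records the ordered list of transformations
applied to it, so any derived analysis variable can state its own provenance.
Missing values are carried as NaN and ignored when estimating location and
scale; transformed outputs keep NaN in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableVector",
    "WinsorSpec",
    "standardize",
    "mad_winsorize",
    "z_winsorize",
    "reverse_code",
    "episodic_composite",
    "global_composite",
]


@dataclass(frozen=True)
class VariableVector:
    """A named per-subject vector with missingness and provenance.

    Parameters
    ----------
    name : str
        Variable name (cohort column).
    values : ndarray
        Float vector, one entry per subject; NaN marks missing.
    provenance : tuple of str
        Ordered names of the transformations already applied.
    """

    name: str
    values: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 1:
            raise ValueError(f"{self.name!r}: values must be 1-dimensional")

    @classmethod
    def from_series(cls, s: pd.Series, name: str | None = None) -> "VariableVector":
        return cls(name=name or str(s.name), values=s.to_numpy(dtype=float))

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_obs(self) -> int:
        return int((~self.missing_mask).sum())

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray, step: str) -> "VariableVector":
        """Return a copy with new values and `step` appended to provenance."""
        return replace(self, values=np.asarray(values, dtype=float),
                       provenance=self.provenance + (step,))


@dataclass(frozen=True)
class WinsorSpec:
    """Winsorization settings.

    method : {"mad", "z"}
        "mad" clamps to median +/- k * b * MAD; "z" clamps standardized
        values at +/- k.
    k : float
        Threshold in robust-scale units (default 3).
    b : float
        MAD scale constant; 1.4826 makes the MAD consistent with the
        standard deviation under normality.
    """

    method: str = "mad"
    k: float = 3.0
    b: float = 1.4826

    def __post_init__(self) -> None:
        if self.method not in ("mad", "z"):
            raise ValueError(f"unknown Winsorization method {self.method!r}")
        if not self.k > 0:
            raise ValueError("Winsorization threshold k must be positive")
        if not self.b > 0:
            raise ValueError("MAD scale constant b must be positive")


def _observed(v: VariableVector) -> np.ndarray:
    obs = v.values[~v.missing_mask]
    return obs


def standardize(v: VariableVector) -> VariableVector:
    """Z-score the non-missing entries (sample SD, ddof=1)."""
    obs = _observed(v)
    if obs.size < 2:
        raise ValueError(f"{v.name!r}: need >= 2 non-missing values to standardize")
    mu = obs.mean()
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{v.name!r}: constant vector cannot be standardized")
    return v.with_values((v.values - mu) / sd, "standardize")


def mad_winsorize(v: VariableVector, spec: WinsorSpec | None = None) -> VariableVector:
    """Clamp values to median +/- k*b*MAD, with MAD = median(|x - median(x)|).

    Values inside the band are untouched. A zero MAD on non-constant data is
    an error: clamping everything to the median would silently destroy the
    variable, so the caller must choose a different scale or variable.
    """
    spec = spec or WinsorSpec()
    obs = _observed(v)
    if obs.size < 2:
        raise ValueError(f"{v.name!r}: need >= 2 non-missing values to Winsorize")
    med = np.median(obs)
    mad = np.median(np.abs(obs - med))
    if mad == 0:
        if np.all(obs == obs[0]):
            # constant data: the clamp is the identity
            return v.with_values(v.values, "mad_winsorize")
        raise ValueError(
            f"{v.name!r}: MAD is zero but data are not constant; "
            "MAD-based Winsorization would collapse all variation. "
            "Consider a z-score-based Winsorization instead."
        )
    half_width = spec.k * spec.b * mad
    lo, hi = med - half_width, med + half_width
    return v.with_values(np.clip(v.values, lo, hi), "mad_winsorize")


def z_winsorize(v: VariableVector, threshold: float = 3.0,
                tol: float = 1e-6) -> VariableVector:
    """Clamp an already-standardized vector at +/- threshold."""
    obs = _observed(v)
    if obs.size < 2:
        raise ValueError(f"{v.name!r}: need >= 2 non-missing values")
    if abs(obs.mean()) > tol or abs(obs.std(ddof=1) - 1) > tol:
        raise ValueError(
            f"{v.name!r}: input to z_winsorize must be standardized "
            f"(mean {obs.mean():.3g}, SD {obs.std(ddof=1):.3g})"
        )
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return v.with_values(np.clip(v.values, -threshold, threshold), "z_winsorize")


def reverse_code(v: VariableVector) -> VariableVector:
    """Negate a (standardized) vector so that higher = better performance.

    Applied to timed tasks, where larger raw values mean slower completion.
    """
    return v.with_values(-v.values, "reverse_code")


def _winsorize_standardize(v: VariableVector, spec: WinsorSpec | None) -> VariableVector:
    return standardize(mad_winsorize(v, spec))


def episodic_composite(immediate: VariableVector, delayed: VariableVector,
                       spec: WinsorSpec | None = None) -> VariableVector:
    """Average of the Winsorized-then-standardized recall scores.

    The composite is missing for a subject whenever either member is.
    """
    if len(immediate) != len(delayed):
        raise ValueError("immediate and delayed recall vectors differ in length")
    imm = _winsorize_standardize(immediate, spec)
    del_ = _winsorize_standardize(delayed, spec)
    vals = (imm.values + del_.values) / 2.0
    return VariableVector(
        name="episodic_memory", values=vals,
        provenance=("mad_winsorize", "standardize", "average_members"),
    )


def global_composite(vectors: Sequence[VariableVector],
                     spec: WinsorSpec | None = None) -> VariableVector:
    """Global-cognition composite over the five cognitive variables.

    Expects exactly five vectors (verbal fluency, processing speed, executive
    function, immediate recall, delayed recall). Each is Winsorized and
    standardized, the five are averaged, and the average is itself Winsorized
    and standardized.
    """
    if len(vectors) != 5:
        raise ValueError(f"global composite requires exactly 5 inputs, got {len(vectors)}")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError("cognition vectors differ in length")
    processed = [_winsorize_standardize(v, spec) for v in vectors]
    mean_vals = np.mean([p.values for p in processed], axis=0)
    avg = VariableVector(
        name="global_cognition", values=mean_vals,
        provenance=("mad_winsorize", "standardize", "average_members"),
    )
    return standardize(mad_winsorize(avg, spec))
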