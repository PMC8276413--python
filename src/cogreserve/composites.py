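"""Enumeration and construction of composite reserve proxies.

A composite proxy is the element-wise mean of two or more standardized
individual proxies. With k individual proxies there are 2^k - k - 1 subsets
of size >= 2, hence 2^k - 1 proxies in total (individual plus composite):
127 for a seven-proxy cohort and 31 for a five-proxy cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import VariableVector

__all__ = [
    "ProxyDefinition",
    "enumerate_composites",
    "build_composite",
    "full_proxy_set",
    "composite_name",
    "write_manifest",
    "read_manifest",
]


@dataclass(frozen=True)
class ProxyDefinition:
    """A named proxy: one individual measure or a composite of several.

    `members` lists the individual proxy names entering the definition
    (length 1 for an individual proxy). `values` is filled in once the
    composite has been built against a cohort.
    """

    name: str
    members: tuple[str, ...]
    values: VariableVector | None = None

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"proxy {self.name!r} repeats a member")
        if len(self.members) == 0:
            raise ValueError("a proxy needs at least one member")

    @property
    def is_composite(self) -> bool:
        return len(self.members) > 1

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)


def composite_name(members: Sequence[str]) -> str:
    """Canonical composite name: members sorted and joined with '+'."""
    return "+".join(sorted(members))


def enumerate_composites(names: Sequence[str]) -> list[ProxyDefinition]:
    """All subsets of size >= 2 of the individual proxies, in a fixed order.

    Ordering is by subset size, then lexicographically within size, over the
    sorted name list — deterministic across runs and platforms.
    """
    names = list(names)
    if len(set(names)) != len(names):
        raise ValueError("individual proxy names must be unique")
    if len(names) < 2:
        raise ValueError("need at least 2 individual proxies to form composites")
    ordered = sorted(names)
    out: list[ProxyDefinition] = []
    for size in range(2, len(ordered) + 1):
        for combo in combinations(ordered, size):
            out.append(ProxyDefinition(name=composite_name(combo), members=combo))
    return out


def build_composite(members: Sequence[VariableVector]) -> VariableVector:
    """Element-wise mean of >= 2 standardized member vectors.

    A subject's composite value is missing whenever any member is missing
    (no prorated mean). Downstream Winsorization is the preprocess module's
    job and is applied to the returned vector by the pipeline.
    """
    if len(members) < 2:
        raise ValueError("a composite requires at least 2 members")
    lengths = {len(m) for m in members}
    if len(lengths) != 1:
        raise ValueError("composite members differ in length")
    vals = np.mean([m.values for m in members], axis=0)  # NaN propagates
    name = composite_name([m.name for m in members])
    return VariableVector(name=name, values=vals, provenance=("average_members",))


def full_proxy_set(names: Sequence[str]) -> list[ProxyDefinition]:
    """Individual proxies followed by every composite: 2^k - 1 definitions."""
    names = list(names)
    if len(set(names)) != len(names):
        raise ValueError("individual proxy names must be unique")
    if len(names) < 1:
        raise ValueError("need at least one proxy name")
    individuals = [ProxyDefinition(name=n, members=(n,)) for n in sorted(names)]
    if len(names) == 1:
        return individuals
    return individuals + enumerate_composites(names)


def write_manifest(proxies: Sequence[ProxyDefinition], path: str | Path) -> None:
    """Serialize proxy definitions (name + members) as JSON."""
    payload = [{"name": p.name, "members": list(p.members)} for p in proxies]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_manifest(path: str | Path) -> list[ProxyDefinition]:
    payload = json.loads(Path(path).read_text())
    return [ProxyDefinition(name=d["name"], members=tuple(d["members"]))
            for d in payload]
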