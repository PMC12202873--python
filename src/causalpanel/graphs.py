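"""Lag-annotated causal graph objects, JSON serialization, and recovery scoring.

A :class:`CausalLink` is one discovered dependence ``source --(lag)--> sink``
with its test record (partial correlation ``rho`` and p-value).  Lagged links
(``lag >= 1``) are always directed by time order; contemporaneous links
(``lag == 0``) may be ``directed``, ``unoriented``, or ``conflict``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "CausalLink",
    "CausalGraph",
    "link_key",
    "read_graph_json",
    "write_graph_json",
    "score_recovery",
]

ORIENTATIONS = ("directed", "unoriented", "conflict")


@dataclass
class CausalLink:
    source: int
    sink: int
    lag: int
    p_value: float | None = None
    rho: float | None = None
    orientation: str = "directed"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.lag == 0 and self.source == self.sink:
            raise ValueError("no self-links at lag 0")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.lag >= 1 and self.orientation != "directed":
            raise ValueError("lagged links are always directed")


def link_key(link: CausalLink) -> tuple[int, int, int]:
    """Canonical identity used to match links across runs.

    Orientation is ignored: a contemporaneous link is identified by its
    unordered endpoint pair, a lagged link by (source, sink, lag).
    """
    if link.lag == 0:
        a, b = sorted((link.source, link.sink))
        return (a, b, 0)
    return (link.source, link.sink, link.lag)


@dataclass
class CausalGraph:
    """The discovered graph: a set of links plus run metadata."""

    n_vars: int
    tau_max: int
    alpha: float
    links: list[CausalLink] = field(default_factory=list)
    names: list[str] | None = None

    def __post_init__(self) -> None:
        for link in self.links:
            if not (0 <= link.source < self.n_vars and 0 <= link.sink < self.n_vars):
                raise ValueError("link endpoint out of range")
            if link.lag > self.tau_max:
                raise ValueError("link lag exceeds tau_max")

    def link_keys(self) -> set[tuple[int, int, int]]:
        return {link_key(l) for l in self.links}

    def parents(self, j: int, min_lag: int = 0) -> set[tuple[int, int]]:
        """Directed parents ``(i, tau)`` of variable ``j`` with ``tau >= min_lag``."""
        return {
            (l.source, l.lag)
            for l in self.links
            if l.sink == j and l.orientation == "directed" and l.lag >= min_lag
        }

    def parent_map(self, min_lag: int = 0) -> dict[int, set[tuple[int, int]]]:
        return {j: self.parents(j, min_lag) for j in range(self.n_vars)}

    def cross_links(self) -> list[CausalLink]:
        return [l for l in self.links if l.source != l.sink]

    def to_dict(self) -> dict:
        return {
            "n_vars": self.n_vars,
            "tau_max": self.tau_max,
            "alpha": self.alpha,
            "names": self.names,
            "links": [asdict(l) for l in self.links],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CausalGraph":
        links = [CausalLink(**d) for d in payload["links"]]
        return cls(
            n_vars=payload["n_vars"],
            tau_max=payload["tau_max"],
            alpha=payload["alpha"],
            links=links,
            names=payload.get("names"),
        )


def write_graph_json(graph: CausalGraph, path) -> None:
    with open(path, "w") as fh:
        json.dump(graph.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_graph_json(path) -> CausalGraph:
    with open(path) as fh:
        return CausalGraph.from_dict(json.load(fh))


def score_recovery(truth: CausalGraph, found: CausalGraph) -> dict:
    """Score a discovered graph against a known ground-truth graph.

    A true link counts as detected when a link with the same canonical key
    (exact lag; unordered endpoints at lag 0) appears in ``found``.  For
    detected links the sign of the recovered ``rho`` is compared with the
    sign of the planted coefficient (stored in ``truth`` links' ``rho``).
    """
    found_by_key = {link_key(l): l for l in found.links}
    records = []
    for true_link in truth.cross_links():
        key = link_key(true_link)
        hit = found_by_key.get(key)
        sign_ok = None
        if hit is not None and hit.rho is not None and true_link.rho is not None:
            sign_ok = bool(np.sign(hit.rho) == np.sign(true_link.rho))
        records.append(
            {
                "key": key,
                "coeff": true_link.rho,
                "detected": hit is not None,
                "sign_ok": sign_ok,
            }
        )
    n_true = len(records)
    n_hit = sum(r["detected"] for r in records)
    truth_keys = {r["key"] for r in records}
    false_links = [l for l in found.cross_links() if link_key(l) not in truth_keys]
    return {
        "links": records,
        "recall": n_hit / n_true if n_true else float("nan"),
        "n_false": len(false_links),
    }
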