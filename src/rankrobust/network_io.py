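"""Reading, cleaning and writing scored undirected edge lists.

Two TSV dialects are supported:

``generic``
    three whitespace/tab-delimited columns ``node_a  node_b  score`` with
    the score a float in [0, 1].
``string_v10``
    same layout, but the score is an integer combined score in 0..999
    which is divided by 1000 on input (so ``400`` becomes ``0.400``).

Lines starting with ``#`` are comments.  A single leading header line is
auto-detected by a non-numeric third field.  Self-loops are dropped and
duplicate unordered pairs are collapsed keeping the **maximum** score
(strongest evidence; the merge policy is a documented choice).
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScoredNetwork",
    "EdgeListParseError",
    "EdgeListValidationError",
    "read_scored_edgelist",
    "write_scored_edgelist",
]


class EdgeListParseError(ValueError):
    """A row could not be parsed (wrong column count, non-numeric score)."""


class EdgeListValidationError(ValueError):
    """A parsed value violates the dialect contract (score out of range)."""


def _canonical_pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class ScoredNetwork:
    """A fixed node universe plus undirected scored edges.

    Invariants (checked on construction): no self-loops, no duplicate
    unordered pairs, every endpoint in ``node_ids``, all scores in [0, 1].
    """

    node_ids: tuple[str, ...]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = tuple(sorted(set(self.node_ids)))
        object.__setattr__(self, "node_ids", ids)
        idset = set(ids)
        clean: dict[tuple[str, str], float] = {}
        for (u, v), s in self.edges.items():
            if u == v:
                raise EdgeListValidationError(f"self-loop on node {u!r}")
            key = _canonical_pair(u, v)
            if key in clean:
                raise EdgeListValidationError(f"duplicate edge {key}")
            if u not in idset or v not in idset:
                raise EdgeListValidationError(f"edge {key} endpoint not in node_ids")
            s = float(s)
            if not 0.0 <= s <= 1.0:
                raise EdgeListValidationError(f"score {s} for edge {key} outside [0, 1]")
            clean[key] = s
        object.__setattr__(self, "edges", clean)

    @classmethod
    def from_edges(
        cls,
        edges: Mapping[tuple[str, str], float],
        extra_nodes: Iterable[str] = (),
    ) -> "ScoredNetwork":
        """Build a network whose node universe is the edge endpoints
        plus ``extra_nodes`` (lets callers pin isolated nodes)."""
        nodes = set(extra_nodes)
        for u, v in edges:
            nodes.add(u)
            nodes.add(v)
        return cls(node_ids=tuple(sorted(nodes)), edges=dict(edges))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def scores(self) -> np.ndarray:
        """Edge scores in canonical (sorted pair) order."""
        return np.array([self.edges[k] for k in sorted(self.edges)], dtype=float)


def _parse_score(token: str, dialect: str, lineno: int) -> float:
    try:
        raw = float(token)
    except ValueError:
        raise EdgeListParseError(
            f"line {lineno}: non-numeric score {token!r}"
        ) from None
    if dialect == "string_v10":
        if not raw.is_integer():
            raise EdgeListValidationError(
                f"line {lineno}: string_v10 scores must be integers, got {token!r}"
            )
        if not 0 <= raw <= 999:
            raise EdgeListValidationError(
                f"line {lineno}: string_v10 score {token!r} outside 0..999"
            )
        return raw / 1000.0
    if dialect == "generic":
        if not 0.0 <= raw <= 1.0:
            raise EdgeListValidationError(
                f"line {lineno}: score {token!r} outside [0, 1]"
            )
        return raw
    raise ValueError(f"unknown dialect {dialect!r}")


def read_scored_edgelist(
    path,
    dialect: str = "generic",
    node_filter: Callable[[str], bool] | None = None,
    extra_nodes: Iterable[str] = (),
) -> ScoredNetwork:
    """Read and clean a scored edge list.

    Parameters
    ----------
    path
        TSV file with at least three columns (node_a, node_b, score).
    dialect
        ``"generic"`` or ``"string_v10"`` (see module docstring).
    node_filter
        Optional predicate on node ids; rows with an endpoint failing the
        predicate are dropped (e.g. to exclude cross-organism proteins).
    extra_nodes
        Extra node ids added to the universe even if isolated.

    Returns
    -------
    ScoredNetwork
        Self-loops dropped, duplicate unordered pairs collapsed to their
        maximum score, node_ids the sorted surviving endpoints.
    """
    if dialect not in ("generic", "string_v10"):
        raise ValueError(f"unknown dialect {dialect!r}")
    edges: dict[tuple[str, str], float] = {}
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                if first_data_line:
                    # could still be a short header; reject for clarity
                    raise EdgeListParseError(
                        f"line {lineno}: expected >=3 columns, got {len(parts)}"
                    )
                raise EdgeListParseError(
                    f"line {lineno}: expected >=3 columns, got {len(parts)}"
                )
            if first_data_line:
                first_data_line = False
                try:
                    float(parts[2])
                except ValueError:
                    continue  # header line
            u, v = parts[0], parts[1]
            score = _parse_score(parts[2], dialect, lineno)
            if u == v:
                continue
            if node_filter is not None and not (node_filter(u) and node_filter(v)):
                continue
            key = _canonical_pair(u, v)
            prev = edges.get(key)
            if prev is None or score > prev:
                edges[key] = score
    return ScoredNetwork.from_edges(edges, extra_nodes=extra_nodes)


def write_scored_edgelist(net: ScoredNetwork, path, comments: Iterable[str] = ()) -> None:
    """Write a 3-column TSV (node_a, node_b, score), scores at 6 decimals.

    ``comments`` lines are written first, prefixed with ``# ``.  Reading
    the file back recovers the edges and scores exactly (isolated nodes
    are not representable in an edge list).
    """
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("node_a\tnode_b\tscore\n")
        for (u, v) in sorted(net.edges):
            fh.write(f"{u}\t{v}\t{net.edges[(u, v)]:.6f}\n")
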