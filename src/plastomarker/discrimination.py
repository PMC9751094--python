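"""In-silico discrimination power of marker panels.

Samples are discriminated by *categorical* allele identity: two samples are
separated by a marker panel iff their allele profiles over the panel
differ. A numeric encoding (SSR repeat count, indel allele length, SNP
category code) exists purely to build Euclidean distance matrices for
UPGMA dendrograms; the discrimination logic itself never thresholds
distances.

The UPGMA implementation uses arithmetic-mean linkage over the original
points, merge height = inter-cluster distance / 2 (molecular-clock
convention), and a deterministic tie-break (smallest lexicographic pair of
cluster representatives). scipy's average linkage is used in the test
suite as an independent oracle, never here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msa_markers import MarkerLocus


@dataclass
class AlleleMatrix:
    """samples x markers table of categorical alleles plus an injective
    per-marker numeric encoding."""

    categorical: pd.DataFrame
    numeric: pd.DataFrame

    def __post_init__(self):
        if self.categorical.empty:
            raise ValueError("allele matrix has no samples or no markers")
        for m in self.categorical.columns:
            cats = self.categorical[m]
            nums = self.numeric[m]
            if cats.nunique() != nums.nunique():
                raise ValueError(f"numeric encoding not injective for marker {m!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.categorical.index)

    @property
    def markers(self) -> list[str]:
        return list(self.categorical.columns)


def encode(markers: list[MarkerLocus], missing: str = "category") -> AlleleMatrix:
    """Build the allele matrix.

    SSR alleles encode as the repeat count, indel alleles as the ungapped
    allele length, SNP bases as stable integer category codes. A sample
    with no allele at a marker either forms its own "missing" category
    (default, distinguishing) or causes the marker to be dropped
    (``missing='drop'``).
    """
    if not markers:
        raise ValueError("no markers to encode")
    samples = sorted({s for m in markers for s in m.alleles})
    cat_cols, num_cols, names = [], [], []
    for m in markers:
        vals = {s: m.alleles.get(s) for s in samples}
        if any(v is None for v in vals.values()):
            if missing == "drop":
                continue
            vals = {s: ("missing" if v is None else v) for s, v in vals.items()}
        cats = pd.Series({s: str(v) for s, v in vals.items()}, name=m.marker_id)
        if m.kind == "ssr":
            nums = pd.Series({s: float(vals[s]) if vals[s] != "missing" else -1.0 for s in samples})
        elif m.kind == "indel":
            nums = pd.Series(
                {
                    s: float(len(str(vals[s]).replace("-", ""))) if vals[s] != "missing" else -1.0
                    for s in samples
                }
            )
            # allele-length encoding may collide for equal-length distinct slices;
            # fall back to category codes to keep the encoding injective
            if nums.nunique() != cats.nunique():
                nums = pd.Series(cats.astype("category").cat.codes.astype(float), index=cats.index)
        else:
            nums = pd.Series(cats.astype("category").cat.codes.astype(float), index=cats.index)
        names.append(m.marker_id)
        cat_cols.append(cats)
        num_cols.append(nums.rename(m.marker_id))
    cat = pd.concat(cat_cols, axis=1) if cat_cols else pd.DataFrame(index=samples)
    num = pd.concat(num_cols, axis=1) if num_cols else pd.DataFrame(index=samples)
    return AlleleMatrix(cat, num)


def euclidean_distances(matrix: AlleleMatrix) -> pd.DataFrame:
    x = matrix.numeric.to_numpy(float)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    return pd.DataFrame(d, index=matrix.samples, columns=matrix.samples)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class DendrogramNode:
    height: float                  # 0 for leaves
    label: str | None = None       # leaf label
    children: tuple = ()

    @property
    def leaves(self) -> list[str]:
        if self.label is not None:
            return [self.label]
        return [l for c in self.children for l in c.leaves]

    def newick(self) -> str:
        return self._nwk(self.height) + ";"

    def _nwk(self, parent_h: float) -> str:
        bl = parent_h - self.height
        if self.label is not None:
            return f"{self.label}:{bl:g}"
        inner = ",".join(c._nwk(self.height) for c in self.children)
        return f"({inner}):{bl:g}"


@dataclass
class Dendrogram:
    root: DendrogramNode
    merges: list[tuple[float, tuple[str, ...], tuple[str, ...]]]  # (height, leavesA, leavesB)

    def newick(self) -> str:
        return self.root.newick()

    def cophenetic(self) -> pd.DataFrame:
        leaves = sorted(self.root.leaves)
        d = pd.DataFrame(0.0, index=leaves, columns=leaves)
        for h, la, lb in self.merges:
            for a in la:
                for b in lb:
                    d.loc[a, b] = d.loc[b, a] = 2.0 * h  # height = distance/2
        return d

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        def ok(node):
            return all(
                c.height <= node.height + tol and ok(c) for c in node.children
            )
        return ok(self.root)


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA on a symmetric, zero-diagonal distance matrix.

    Average linkage is weighted by original cluster sizes (true arithmetic
    mean over all point pairs). Among tied minimal distances the pair whose
    (smallest-leaf, smallest-leaf) ids sort first is merged.
    """
    d = dist.to_numpy(float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if (np.diag(d) != 0).any() or (d < 0).any():
        raise ValueError("distance matrix must be non-negative with zero diagonal")
    labels = list(dist.index)
    nodes = {i: DendrogramNode(0.0, label=labels[i]) for i in range(len(labels))}
    sizes = {i: 1 for i in nodes}
    reps = {i: labels[i] for i in nodes}  # smallest leaf id per cluster
    dmat = {frozenset((i, j)): d[i, j] for i in nodes for j in nodes if i < j}
    merges = []
    nxt = len(labels)
    while len(nodes) > 1:
        best_key, best = None, None
        for key, val in dmat.items():
            i, j = sorted(key, key=lambda x: reps[x])
            tb = (val, reps[i], reps[j])
            if best is None or tb < best:
                best, best_key = tb, key
        i, j = sorted(best_key, key=lambda x: reps[x])
        h = best[0] / 2.0
        node = DendrogramNode(h, children=(nodes[i], nodes[j]))
        merges.append((h, tuple(nodes[i].leaves), tuple(nodes[j].leaves)))
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = dmat.pop(frozenset((i, k)))
            djk = dmat.pop(frozenset((j, k)))
            dmat[frozenset((nxt, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        dmat.pop(frozenset((i, j)))
        nodes[nxt] = node
        sizes[nxt] = sizes[i] + sizes[j]
        reps[nxt] = min(reps[i], reps[j])
        for k in (i, j):
            del nodes[k], sizes[k], reps[k]
        nxt += 1
    root = next(iter(nodes.values()))
    return Dendrogram(root, merges)


# ---------------------------------------------------------------------------
# discrimination power


def discrimination_power(
    matrix: AlleleMatrix, subset: list[str] | None = None
) -> list[list[str]]:
    """Partition of samples into identity groups: samples sharing the same
    categorical allele profile over ``subset`` fall in one group. Fully
    discriminated iff every group is a singleton."""
    cols = list(matrix.markers if subset is None else subset)
    if not cols:
        raise ValueError("marker subset is empty")
    prof = matrix.categorical[cols]
    groups: dict[tuple, list[str]] = {}
    for s in matrix.samples:
        groups.setdefault(tuple(prof.loc[s]), []).append(s)
    return sorted(groups.values(), key=lambda g: g[0])


def _separates(matrix: AlleleMatrix, cols, required_pairs) -> bool:
    prof = matrix.categorical[list(cols)]
    return all(
        tuple(prof.loc[a]) != tuple(prof.loc[b]) for a, b in required_pairs
    )


@dataclass
class MinimalSetResult:
    achievable: bool
    size: int | None
    subsets: list[tuple[str, ...]]
    inseparable: list[list[str]]   # non-singleton groups under the full panel
    optimal: bool = True           # False for the greedy fallback


def minimal_marker_set(
    matrix: AlleleMatrix,
    target: list[list[str]] | None = None,
    exhaustive_max: int = 25,
) -> MinimalSetResult:
    """Smallest marker subsets whose identity partition separates every
    pair of samples that ``target`` separates (default target: all
    singletons). Exhaustive by increasing subset size for panels up to
    ``exhaustive_max`` markers; a greedy set-cover fallback (flagged
    non-optimal) is used beyond that."""
    samples = matrix.samples
    if target is None:
        target = [[s] for s in samples]
    group_of = {}
    for gi, grp in enumerate(target):
        for s in grp:
            group_of[s] = gi
    required = [
        (a, b)
        for a, b in itertools.combinations(samples, 2)
        if group_of.get(a) != group_of.get(b)
    ]
    markers = matrix.markers
    if not _separates(matrix, markers, required):
        full = discrimination_power(matrix)
        return MinimalSetResult(False, None, [], [g for g in full if len(g) > 1])
    if len(markers) <= exhaustive_max:
        for size in range(1, len(markers) + 1):
            hits = [
                tuple(sub)
                for sub in itertools.combinations(markers, size)
                if _separates(matrix, sub, required)
            ]
            if hits:
                return MinimalSetResult(True, size, hits, [])
        raise AssertionError("unreachable: full panel separates but no subset found")
    # greedy: repeatedly add the marker separating the most unresolved pairs
    chosen: list[str] = []
    todo = list(required)
    while todo:
        scores = {
            m: sum(
                matrix.categorical.loc[a, m] != matrix.categorical.loc[b, m]
                for a, b in todo
            )
            for m in markers
            if m not in chosen
        }
        best = max(sorted(scores), key=lambda m: scores[m])
        chosen.append(best)
        todo = [
            (a, b)
            for a, b in todo
            if matrix.categorical.loc[a, best] == matrix.categorical.loc[b, best]
        ]
    return MinimalSetResult(True, len(chosen), [tuple(chosen)], [], optimal=False)
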