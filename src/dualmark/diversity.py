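"""Panel diversity statistics and neighbor-joining dendrogram.

Per-locus statistics follow marker-survey conventions: Na is the number of
distinct alleles, Ho the observed heterozygote fraction, PIC the
uncorrected 1 - sum(Pi^2) over allele frequencies Pi, and He Nei's unbiased
expected heterozygosity (2n/(2n-1)) * (1 - sum(Pi^2)) over n diploid
individuals — the small-sample correction is why He can marginally exceed
the biallelic 0.5 ceiling.

The dendrogram route scores every (locus, allele) column for presence (1) or
absence (0) per sample, computes a similarity coefficient (simple matching
by default; Jaccard and Dice as options) with pairwise deletion over missing
calls, and clusters the resulting distance (1 - s) matrix with classical
neighbor joining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "PanelCall",
    "GenotypePanel",
    "LocusDiversity",
    "filter_panel_calls",
    "locus_stats",
    "panel_stats",
    "binary_matrix",
    "similarity_matrix",
    "neighbor_joining",
    "write_newick",
    "read_newick",
]


@dataclass(frozen=True)
class PanelCall:
    """One diploid genotype call with confidence fields."""

    alleles: tuple[str, str]  # unordered; stored sorted
    depth: int
    quality: float
    reads_per_allele: dict[str, int] = field(default_factory=dict, hash=False)


@dataclass
class GenotypePanel:
    """Loci x samples allele calls; missing calls simply absent from ``calls``."""

    loci: list[str]
    samples: list[str]
    calls: dict[tuple[str, str], PanelCall]  # (locus, sample) -> call

    def genotype(self, locus: str, sample: str) -> tuple[str, str] | None:
        c = self.calls.get((locus, sample))
        return c.alleles if c is not None else None


@dataclass(frozen=True)
class LocusDiversity:
    locus: str
    na: int
    ho: float
    he: float
    pic: float
    frequencies: dict[str, float]
    monomorphic: bool


def filter_panel_calls(
    panel: GenotypePanel,
    min_depth: int = 15,
    min_quality: float = 30.0,
    min_allele_reads: int = 4,
) -> GenotypePanel:
    """Set low-confidence calls to missing.

    A call survives iff depth > ``min_depth``, quality > ``min_quality``
    (both strict) and every allele it carries has >= ``min_allele_reads``
    supporting reads (inclusive).  Loci left with fewer than two calls are
    logged; downstream statistics skip them.
    """
    kept: dict[tuple[str, str], PanelCall] = {}
    for key, c in panel.calls.items():
        if c.depth <= min_depth or c.quality <= min_quality:
            continue
        observed = set(c.alleles)
        if any(c.reads_per_allele.get(a, 0) < min_allele_reads for a in observed):
            continue
        kept[key] = c
    out = GenotypePanel(loci=list(panel.loci), samples=list(panel.samples), calls=kept)
    for locus in out.loci:
        n = sum(1 for s in out.samples if (locus, s) in kept)
        if n < 2:
            logger.info("locus %s has %d calls after filtering; excluded from stats", locus, n)
    return out


def locus_stats(panel: GenotypePanel, locus: str) -> LocusDiversity | None:
    """Na / Ho / He / PIC for one locus; None with < 2 non-missing calls.

    PIC = 1 - sum(Pi^2) exactly; He applies Nei's (2n/(2n-1)) correction.
    A monomorphic locus yields Na=1 and zero Ho/He/PIC, flagged.
    """
    genos = [
        panel.calls[(locus, s)].alleles
        for s in panel.samples
        if (locus, s) in panel.calls
    ]
    n = len(genos)
    if n < 2:
        return None
    counts: dict[str, int] = {}
    het = 0
    for a1, a2 in genos:
        counts[a1] = counts.get(a1, 0) + 1
        counts[a2] = counts.get(a2, 0) + 1
        if a1 != a2:
            het += 1
    total = 2 * n
    freqs = {a: c / total for a, c in counts.items()}
    sum_p2 = sum(p * p for p in freqs.values())
    pic = 1.0 - sum_p2
    he = (total / (total - 1)) * (1.0 - sum_p2)
    ho = het / n
    return LocusDiversity(
        locus=locus, na=len(counts), ho=ho, he=he, pic=pic,
        frequencies=freqs, monomorphic=len(counts) == 1,
    )


def panel_stats(panel: GenotypePanel) -> list[LocusDiversity]:
    """Per-locus diversity over all loci with >= 2 non-missing calls."""
    out = []
    for locus in panel.loci:
        s = locus_stats(panel, locus)
        if s is not None:
            out.append(s)
    return out


def binary_matrix(panel: GenotypePanel) -> tuple[np.ma.MaskedArray, list[str]]:
    """Samples x (locus, allele) presence/absence matrix.

    Cell = 1 iff the sample carries that allele at that locus; both cells of
    a missing call are masked (excluded pairwise from similarity).  Returns
    the masked matrix and the column labels "locus:allele".
    """
    columns: list[tuple[str, str]] = []
    for locus in panel.loci:
        alleles = sorted(
            {
                a
                for s in panel.samples
                for a in (panel.genotype(locus, s) or ())
            }
        )
        columns.extend((locus, a) for a in alleles)
    mat = np.ma.masked_all((len(panel.samples), len(columns)), dtype=float)
    for j, (locus, allele) in enumerate(columns):
        for i, sample in enumerate(panel.samples):
            g = panel.genotype(locus, sample)
            if g is None:
                continue
            mat[i, j] = 1.0 if allele in g else 0.0
    return mat, [f"{l}:{a}" for l, a in columns]


def similarity_matrix(
    matrix: np.ma.MaskedArray,
    coefficient: str = "sm",
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise similarity and distance (1 - s) from a binary matrix.

    ``coefficient``: "sm" (simple matching, default), "jaccard" or "dice".
    Masked cells are deleted pairwise.  Raises if a sample pair has no
    comparable cells.
    """
    n = matrix.shape[0]
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = matrix[i], matrix[j]
            valid = ~(np.ma.getmaskarray(a) | np.ma.getmaskarray(b))
            if not valid.any():
                raise ValueError(f"samples {i} and {j} share no comparable cells")
            x = np.asarray(a[valid], dtype=float)
            y = np.asarray(b[valid], dtype=float)
            m11 = float(np.sum((x == 1) & (y == 1)))
            m00 = float(np.sum((x == 0) & (y == 0)))
            m_mismatch = float(np.sum(x != y))
            if coefficient == "sm":
                s = (m11 + m00) / (m11 + m00 + m_mismatch)
            elif coefficient == "jaccard":
                denom = m11 + m_mismatch
                s = m11 / denom if denom else 1.0
            elif coefficient == "dice":
                denom = 2 * m11 + m_mismatch
                s = 2 * m11 / denom if denom else 1.0
            else:
                raise ValueError(f"unknown coefficient {coefficient!r}")
            sim[i, j] = sim[j, i] = s
    return sim, 1.0 - sim


def neighbor_joining(
    distances: np.ndarray,
    labels: list[str],
) -> TreeNode:
    """Classical neighbor joining on a symmetric zero-diagonal matrix.

    Agglomerates by the Q criterion; ties are broken by the lowest (i, j)
    index pair, so the result is deterministic.  Negative branch lengths are
    clamped to zero with the deficit logged.  Returns an unrooted tree
    (trifurcating root) over ``labels``.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if len(labels) != n:
        raise ValueError("need one label per row")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    d = d.copy()
    active = list(range(n))

    def clamp(x: float, where: str) -> float:
        if x < 0:
            logger.info("negative branch length %.3g at %s clamped to 0", x, where)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among minima for determinism
        flat = np.round(q, 12)
        best = np.argwhere(flat == flat.min())
        bi, bj = min((min(i, j), max(i, j)) for i, j in best)
        i, j = active[bi], active[bj]
        dij = d[i, j]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, nodes[i].name or "internal"), clamp(lj, nodes[j].name or "internal")
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        # distances from the new node
        newd = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, newd])
        newcol = np.append(newd, 0.0)
        d = np.column_stack([d, newcol])
        nodes.append(new)
        k = d.shape[0] - 1
        active = [a for a in active if a not in (i, j)] + [k]

    # final three-way join (three-point formulas)
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].length = clamp(li, nodes[i].name or "internal")
    nodes[j].length = clamp(lj, nodes[j].name or "internal")
    nodes[k].length = clamp(lk, nodes[k].name or "internal")
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return root


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick with 6-decimal branch lengths."""
    t = tree.copy()
    for node in t.traverse():
        if node.length is not None:
            node.length = float(f"{node.length:.6f}")
    return str(t).strip()


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string; raises on malformed input."""
    from io import StringIO

    try:
        return TreeNode.read(StringIO(text))
    except Exception as exc:  # skbio raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
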