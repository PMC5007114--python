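"""Topology testing: alternative-topology generation, the approximately
unbiased (AU) test, and internode certainty (IC).

``generate_alternative_topologies`` slides a clade "up and down" the path
towards a second clade: the clade is pruned and reattached successively on
each edge of the inter-clade path, which on the Firmicutes reference
topology reproduces the 6 + 6 = 12 alternative placements of the two
diderm lineages (Negativicutes, Halanaerobiales).

``rell_bootstrap`` + ``au_pvalues`` implement the multiscale-bootstrap AU
test: per-site log-likelihoods are resampled (RELL - no re-optimisation)
at several scale factors r, the proportion of resamples in which each
topology is best is recorded, and the scaling law BP(r) = 1 - Phi(d sqrt r
+ c / sqrt r) is fitted by weighted least squares on the probit scale;
p_AU = 1 - Phi(d - c).

``internode_certainty`` scores each internode of a reference tree against
a set of (possibly partial, possibly multifurcating) gene trees: gene-tree
branches below a bootstrap-support threshold are collapsed first, and the
internode's split is compared with the most frequent conflicting split;
IC = 1 - H2(p1) with the sign indicating whether the reference split or
its best rival is the more frequent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .phylo_core import (
    Bipartition,
    InvalidMoveError,
    Tree,
    _detach,
    bipartitions,
    collapse_low_support,
    regraft,
)

__all__ = [
    "generate_alternative_topologies",
    "BPTable",
    "rell_bootstrap",
    "AURow",
    "AUResult",
    "au_pvalues",
    "ICRecord",
    "ICAnnotation",
    "internode_certainty",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


# ---------------------------------------------------------------------------
# Alternative topologies by clade sliding
# ---------------------------------------------------------------------------

def generate_alternative_topologies(
    tree: Tree,
    clade: frozenset[str] | set[str],
    n_positions: int,
    toward: frozenset[str] | set[str],
    label_prefix: str = "X",
) -> list[tuple[str, Tree]]:
    """Slide ``clade`` along the path toward (and past) ``toward``.

    The clade is pruned; the candidate reattachment edges are the
    successive edges of the path from its original attachment point to the
    ``toward`` clade, the last of them being the ``toward`` clade's own
    edge (reattaching there clusters the two clades).  Position ``i`` is
    labelled ``{label_prefix}{i}``.  Raises :class:`InvalidMoveError` if
    the path offers fewer than ``n_positions`` edges.
    """
    clade = frozenset(clade)
    toward = frozenset(toward)
    if clade & toward:
        raise InvalidMoveError("clade and toward sets overlap")
    if n_positions == 0:
        return []
    pruned = tree.copy()
    node = pruned.find_edge(clade)  # KeyError -> clade not monophyletic
    parent = node.parent
    siblings = [c for c in parent.children if c is not node]
    merged = siblings[0] if (parent.parent is not None and len(siblings) == 1) else None
    _detach(pruned, node)
    start = merged if merged is not None else (
        siblings[0].parent if siblings[0].parent is not None else pruned.root
    )
    goal = pruned.find_edge(toward)
    path_edges = _edge_path(pruned, start, goal)
    if merged is not None and path_edges and path_edges[0] is merged:
        path_edges = path_edges[1:]
    out = []
    ref_key = bipartitions(tree)
    seen = {ref_key}
    for edge in path_edges:
        if len(out) == n_positions:
            break
        target = edge.tip_set()
        alt = regraft(tree, clade, target)
        key = bipartitions(alt)
        if key in seen:
            # a path edge can re-create the original attachment (e.g. the
            # two rooted halves of one unrooted edge at a degree-2 root)
            continue
        seen.add(key)
        out.append((f"{label_prefix}{len(out) + 1}", alt))
    if len(out) < n_positions:
        raise InvalidMoveError(
            f"only {len(out)} candidate positions available along the "
            f"path (requested {n_positions})"
        )
    return out


def _edge_path(tree: Tree, start, goal) -> list:
    """Edges (child nodes) along the tree path from node ``start`` to node
    ``goal``, ignoring the rooting (paths may cross the root)."""
    # parents chains to root
    def chain(n):
        out = [n]
        while out[-1].parent is not None:
            out.append(out[-1].parent)
        return out

    up_start = chain(start)
    up_goal = chain(goal)
    in_goal = {id(n): i for i, n in enumerate(up_goal)}
    for k, n in enumerate(up_start):
        if id(n) in in_goal:
            meet = in_goal[id(n)]
            # edges: start..meet (each node's own parent edge), then down
            up = up_start[:k]
            down = up_goal[:meet]
            return up + list(reversed(down))
    raise RuntimeError("disconnected tree")  # pragma: no cover


# ---------------------------------------------------------------------------
# Site log-likelihood matrices for candidate topologies
# ---------------------------------------------------------------------------

def sitell_matrix(
    topologies: list[tuple[str, Tree]],
    alignment,
    model,
    optimize_alpha: bool = True,
    share_alpha: bool = False,
    init_length: float = 0.1,
    tol: float = 1e-3,
) -> tuple[list[str], np.ndarray]:
    """Per-site log-likelihoods of every candidate topology on one
    alignment, after per-topology branch-length optimisation.

    Topologies arriving without meaningful branch lengths (missing or zero)
    are initialised to ``init_length`` before optimisation.  With
    ``share_alpha`` the gamma shape is estimated once, on the first
    topology, and reused for the rest; otherwise it is re-optimised per
    topology."""
    from .likelihood import optimize_branch_lengths, site_log_likelihoods

    labels, rows = [], []
    current = model
    for idx, (label, topo) in enumerate(topologies):
        t = topo.copy()
        for n in t.postorder():
            if n.parent is not None and (n.length is None or n.length <= 0):
                n.length = init_length
        do_alpha = optimize_alpha and (not share_alpha or idx == 0)
        t_opt, _, alpha = optimize_branch_lengths(
            t, alignment, current, optimize_alpha=do_alpha, tol=tol
        )
        fitted = current.with_alpha(alpha)
        if share_alpha and idx == 0:
            current = fitted
        rows.append(site_log_likelihoods(t_opt, alignment, fitted))
        labels.append(label)
    return labels, np.vstack(rows)


# ---------------------------------------------------------------------------
# Multiscale RELL bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BPTable:
    """Bootstrap proportions of each topology being best, per scale.

    ``bp[s, k]`` is the proportion of replicates at scale ``scales[s]`` in
    which topology ``labels[k]`` attains the maximum resampled
    log-likelihood (ties split equally); rows sum to 1.
    """

    labels: list[str]
    scales: np.ndarray
    bp: np.ndarray  # (n_scales, n_topologies)
    n_boot: int
    sizes: np.ndarray = field(default=None)  # resampled sites per scale


def rell_bootstrap(
    sitell: np.ndarray,
    scales=DEFAULT_SCALES,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    labels: list[str] | None = None,
) -> BPTable:
    """Resampling-of-estimated-log-likelihoods bootstrap over several
    resample-size scales.

    ``sitell`` has one row per topology and one column per site.  At scale
    ``r``, each replicate draws ``ceil(r * n_sites)`` site indices with
    replacement and sums the per-site log-likelihoods; the best topology is
    tallied (exact ties split equally)."""
    sitell = np.asarray(sitell, dtype=float)
    if sitell.ndim != 2 or sitell.shape[0] < 2:
        raise ValueError("need a matrix with at least two topologies")
    if n_boot < 100:
        warnings.warn(
            "fewer than 100 RELL replicates per scale gives an unstable "
            "AU fit", stacklevel=2,
        )
    scales = np.asarray(scales, dtype=float)
    if (scales <= 0).any():
        raise ValueError("scales must be positive")
    k, n = sitell.shape
    if labels is None:
        labels = [f"T{i}" for i in range(k)]
    rng = np.random.default_rng(seed)
    bp = np.zeros((len(scales), k))
    sizes = np.ceil(scales * n).astype(int)
    for s, m in enumerate(sizes):
        chunk = max(1, int(2e7 / (k * m)))
        done = 0
        while done < n_boot:
            b = min(chunk, n_boot - done)
            idx = rng.integers(0, n, size=(b, m))
            totals = sitell[:, idx].sum(axis=2)  # (k, b)
            best = totals.max(axis=0)
            is_best = np.abs(totals - best[None, :]) <= 1e-10 * np.maximum(
                1.0, np.abs(best[None, :])
            )
            bp[s] += (is_best / is_best.sum(axis=0, keepdims=True)).sum(axis=1)
            done += b
    bp /= n_boot
    return BPTable(labels=list(labels), scales=scales, bp=bp, n_boot=n_boot,
                   sizes=sizes)


# ---------------------------------------------------------------------------
# AU p-values
# ---------------------------------------------------------------------------

@dataclass
class AURow:
    label: str
    p_au: float
    d: float
    c: float
    diagnostic: str = "ok"


@dataclass
class AUResult:
    rows: list[AURow]

    def __getitem__(self, label: str) -> AURow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def p_values(self) -> dict[str, float]:
        return {r.label: r.p_au for r in self.rows}

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"topology": r.label, "p_au": r.p_au, "d": r.d, "c": r.c,
                 "diagnostic": r.diagnostic}
                for r in self.rows
            ]
        )


def au_pvalues(bp_table: BPTable) -> AUResult:
    """Fit the multiscale-bootstrap scaling law and return AU p-values.

    For each topology, BP(r) is modelled as 1 - Phi(d sqrt(r) + c/sqrt(r));
    d and c are estimated by weighted least squares on the probit scale
    with binomial-information weights, and p_AU = 1 - Phi(d - c).
    Topologies that win (or lose) every replicate at every scale are
    short-circuited to p = 1 (or 0); if the fit degenerates the bootstrap
    proportion at the scale nearest 1 is reported with a diagnostic flag.
    """
    rows = []
    scales = np.asarray(bp_table.scales, dtype=float)
    n_boot = bp_table.n_boot
    for j, label in enumerate(bp_table.labels):
        bp = bp_table.bp[:, j]
        if np.all(bp >= 1.0 - 1e-12):
            rows.append(AURow(label, 1.0, -np.inf, 0.0, "degenerate: always best"))
            continue
        if np.all(bp <= 1e-12):
            rows.append(AURow(label, 0.0, np.inf, 0.0, "degenerate: never best"))
            continue
        usable = (bp > 0) & (bp < 1)
        if usable.sum() < 2:
            r1 = int(np.argmin(np.abs(scales - 1.0)))
            rows.append(AURow(label, float(bp[r1]), np.nan, np.nan,
                              "fit failure: too few informative scales"))
            continue
        r = scales[usable]
        p = bp[usable]
        z = norm.ppf(1.0 - p)
        w = n_boot * norm.pdf(z) ** 2 / (p * (1.0 - p))
        X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            r1 = int(np.argmin(np.abs(scales - 1.0)))
            rows.append(AURow(label, float(bp[r1]), np.nan, np.nan,
                              "fit failure: singular system"))
            continue
        d, c = float(beta[0]), float(beta[1])
        p_au = float(norm.sf(d - c))
        rows.append(AURow(label, p_au, d, c))
    return AUResult(rows)


# ---------------------------------------------------------------------------
# Internode certainty
# ---------------------------------------------------------------------------

@dataclass
class ICRecord:
    bipartition: Bipartition
    ic: float | None  # None = no informative gene tree
    support: int
    conflict: int
    best_conflicting: Bipartition | None = None


@dataclass
class ICAnnotation:
    records: dict[Bipartition, ICRecord]

    def value(self, bp: Bipartition) -> float | None:
        return self.records[bp].ic

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "bipartition": repr(bp),
                    "ic": rec.ic,
                    "support": rec.support,
                    "conflict": rec.conflict,
                }
                for bp, rec in sorted(
                    self.records.items(), key=lambda kv: repr(kv[0])
                )
            ]
        )

    def annotate(self, tree: Tree) -> Tree:
        """A copy of ``tree`` with IC values written into the support slot
        of each internal edge (missing values left unset)."""
        out = tree.copy()
        taxa = out.tip_labels()
        for node in out.postorder():
            if node.is_tip or node is out.root:
                continue
            bp = Bipartition(taxa, node.tip_set())
            rec = self.records.get(bp)
            node.support = None if rec is None or rec.ic is None else round(
                rec.ic, 4
            )
        return out


def _entropy2(p1: float) -> float:
    p2 = 1.0 - p1
    h = 0.0
    for p in (p1, p2):
        if p > 0:
            h -= p * math.log2(p)
    return h


def internode_certainty(
    ref: Tree,
    gene_trees: list[Tree],
    support_threshold: float = 70.0,
    include_partial: bool = True,
) -> ICAnnotation:
    """Internode certainty of every reference internode against a set of
    gene trees.

    Gene-tree edges with bootstrap support strictly below
    ``support_threshold`` percent are collapsed first.  For a reference
    split B, each gene tree is restricted to the taxa it shares with both
    sides of B; it counts as *support* if its split set contains the
    restricted B, as *conflict* if it contains a split incompatible with
    the restricted B.  With f1 the support count and f2 the count of the
    single most frequent conflicting split, IC = (1 - H2(f1/(f1+f2)))
    signed negative when the rival split is the more frequent.  Internodes
    no gene tree is informative for are reported as missing.

    With ``include_partial`` false, gene trees lacking any reference taxon
    are skipped entirely.
    """
    taxa = ref.tip_labels()
    prepared = []
    for g in gene_trees:
        if not include_partial and g.tip_labels() != taxa:
            continue
        collapsed = collapse_low_support(g, support_threshold)
        prepared.append(
            (collapsed.tip_labels() & taxa, bipartitions(collapsed))
        )
    records = {}
    for B in bipartitions(ref):
        side1 = B.side
        side2 = taxa - B.side
        f_support = 0
        conflict_counts: dict[tuple, int] = {}
        conflict_splits: dict[tuple, Bipartition] = {}
        informative = 0
        for g_taxa, g_splits in prepared:
            shared = g_taxa & taxa
            if not (shared & side1) or not (shared & side2):
                continue
            B_r = B.restrict(shared)
            if B_r is None or B_r.is_trivial():
                continue
            supported = False
            conflicts_here = set()
            for g in g_splits:
                g_r = g.restrict(shared)
                if g_r is None or g_r.is_trivial():
                    continue
                if g_r == B_r:
                    supported = True
                elif g_r.conflicts_with(B_r):
                    conflicts_here.add(g_r)
            if supported:
                f_support += 1
                informative += 1
            elif conflicts_here:
                informative += 1
                for g_r in conflicts_here:
                    key = (g_r.taxa, g_r.side)
                    conflict_counts[key] = conflict_counts.get(key, 0) + 1
                    conflict_splits[key] = g_r
        if informative == 0:
            records[B] = ICRecord(B, None, 0, 0)
            continue
        if not conflict_counts:
            records[B] = ICRecord(B, 1.0, f_support, 0)
            continue
        best_key = max(
            conflict_counts,
            key=lambda k: (conflict_counts[k], tuple(sorted(k[1]))),
        )
        f_conflict = conflict_counts[best_key]
        p1 = f_support / (f_support + f_conflict)
        ic = 1.0 - _entropy2(p1)
        if f_conflict > f_support:
            ic = -ic
        records[B] = ICRecord(B, ic, f_support, f_conflict,
                              conflict_splits[best_key])
    return ICAnnotation(records)
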