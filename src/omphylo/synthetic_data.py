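"""Synthetic inputs for every stage of the pipeline.

The real study started from a database of complete genomes; at desk scale
those inputs are replaced by simulation:

* per-marker amino-acid alignments evolved under LG+Gamma(4) along a given
  tree (:func:`simulate_alignment`),
* incongruent, partially sampled gene trees obtained by random SPR moves
  and taxon deletion (:func:`perturb_gene_trees`),
* ortholog presence/absence tables with missing taxa and paralog flags
  (:func:`generate_ortholog_table`),
* the eight-lineage schematic Firmicutes topology with diderm/monoderm tip
  states (:func:`firmicutes_fixture`).

All generators are pure functions of their ``seed``.

The LG model ships as a data file in the PAML ``.dat`` layout (lower
triangle of exchangeabilities, then stationary frequencies).  A Poisson
model (all exchangeabilities and frequencies equal) is bundled alongside:
its transition probabilities have a closed form, which the test suite uses
as an analytic oracle.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .phylo_core import (
    AA_ALPHABET,
    Alignment,
    Node,
    Tree,
    bipartitions,
    parse_newick,
    restrict_to,
    spr,
)

__all__ = [
    "SubstModel",
    "OrthologTable",
    "discrete_gamma_rates",
    "simulate_alignment",
    "perturb_gene_trees",
    "generate_ortholog_table",
    "firmicutes_fixture",
    "random_tree",
]

N = 20  # amino-acid states


def discrete_gamma_rates(alpha: float, n_cat: int = 4) -> np.ndarray:
    """Category rates of the discretised Gamma(alpha, alpha) distribution
    with ``n_cat`` equal-probability categories, each category represented
    by its conditional mean.  The rates average to 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    if n_cat < 1:
        raise ValueError("need at least one rate category")
    if n_cat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, n_cat + 1), a=alpha, scale=1.0 / alpha)
    # E[X; a<X<b] for X ~ Gamma(alpha, rate alpha) is the CDF increment of
    # Gamma(alpha+1, rate alpha); each category has probability 1/n_cat
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    rates = n_cat * (upper - lower)
    return rates / rates.mean() * 1.0  # exact unit mean despite tail rounding


@dataclass
class SubstModel:
    """A reversible amino-acid substitution model with discrete-gamma rate
    heterogeneity.

    Parameters
    ----------
    exchangeabilities : (20, 20) symmetric matrix, zero diagonal.
    freqs : stationary frequencies, summing to 1.
    alpha : gamma shape of among-site rate variation.
    n_cat : number of equal-probability rate categories (4 = the usual
        "Gamma4" discretisation).
    """

    exchangeabilities: np.ndarray
    freqs: np.ndarray
    alpha: float = 1.0
    n_cat: int = 4
    name: str = "custom"
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.exchangeabilities.shape != (N, N):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if abs(self.freqs.sum() - 1.0) > 1e-6:
            raise ValueError("stationary frequencies must sum to 1")
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")

    # -- model loading ------------------------------------------------------

    @classmethod
    def load(cls, name: str = "lg", alpha: float = 1.0, n_cat: int = 4) -> "SubstModel":
        """Load a bundled model ("lg" or "poisson") or a PAML-layout .dat
        file given by path."""
        if name in ("lg", "poisson"):
            ref = importlib.resources.files("omphylo") / "data" / f"{name}.dat"
            text = ref.read_text()
            model_name = name
        else:
            with open(name) as fh:
                text = fh.read()
            model_name = name
        rows = [
            [float(x) for x in line.split()]
            for line in text.splitlines()
            if line.strip()
        ]
        tri, freqs = rows[:-1], np.array(rows[-1])
        if len(tri) != N - 1 or any(len(r) != i + 1 for i, r in enumerate(tri)):
            raise ValueError("malformed PAML dat file: bad lower triangle")
        ex = np.zeros((N, N))
        for i, row in enumerate(tri, start=1):
            ex[i, : len(row)] = row
        ex = ex + ex.T
        # .dat files list states in the PAML order; re-index into the
        # package's alphabetical state order
        paml_order = "ARNDCQEGHILKMFPSTWYV"
        perm = np.array([paml_order.index(c) for c in AA_ALPHABET])
        ex = ex[np.ix_(perm, perm)]
        freqs = freqs[perm]
        return cls(ex, freqs, alpha=alpha, n_cat=n_cat, name=model_name)

    def with_alpha(self, alpha: float) -> "SubstModel":
        return SubstModel(
            self.exchangeabilities, self.freqs, alpha=alpha, n_cat=self.n_cat,
            name=self.name,
        )

    # -- rate matrix and transition probabilities ---------------------------

    @property
    def rate_matrix(self) -> np.ndarray:
        """The rate matrix Q = S diag(pi), scaled to one expected
        substitution per unit branch length (-sum pi_i Q_ii = 1)."""
        Q = self.exchangeabilities * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(self.freqs * np.diag(Q)).sum()
        return Q / scale

    def _eigendecomposition(self):
        if self._eig is None:
            Q = self.rate_matrix
            sqrt_pi = np.sqrt(self.freqs)
            # symmetrise: B = D^1/2 Q D^-1/2 shares Q's eigenvalues
            B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
            w, U = np.linalg.eigh((B + B.T) / 2.0)
            left = U.T * sqrt_pi[None, :]          # U^T D^1/2
            right = U / sqrt_pi[:, None]           # D^-1/2 U
            self._eig = (w, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are parent states."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        w, right, left = self._eigendecomposition()
        P = (right * np.exp(w * t)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_cat)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def simulate_alignment(
    tree: Tree,
    model: SubstModel,
    n_sites: int,
    seed: int | np.random.Generator,
) -> Alignment:
    """Evolve ``n_sites`` independent amino-acid columns along ``tree``.

    Root states are drawn from the stationary frequencies; each site is
    assigned one gamma rate category for the whole tree; child states are
    drawn from exp(Q r_c t) down each branch.  The rooting of ``tree`` is
    used as the simulation root (any rooting gives the same distribution
    under a reversible model).
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = np.random.default_rng(seed)
    rates = model.category_rates()
    cats = rng.integers(0, model.n_cat, size=n_sites)
    states: dict[int, np.ndarray] = {}
    root_states = rng.choice(N, size=n_sites, p=model.freqs)
    states[id(tree.root)] = root_states
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(n_sites, dtype=np.int64)
        t = node.length if node.length is not None else 0.0
        for c, r in enumerate(rates):
            mask = cats == c
            if not mask.any():
                continue
            if t * r == 0.0:
                child[mask] = parent_states[mask]
                continue
            cum = model.transition_matrix(t * r).cumsum(axis=1)
            u = rng.random(mask.sum())
            child[mask] = (u[:, None] > cum[parent_states[mask]]).sum(axis=1)
        states[id(node)] = child
    tips = tree.tips()
    mat = np.array([states[id(tip)] for tip in tips], dtype=np.uint8)
    return Alignment([tip.label for tip in tips], mat)


# ---------------------------------------------------------------------------
# Gene-tree perturbation
# ---------------------------------------------------------------------------

def _random_spr(tree: Tree, rng: np.random.Generator, max_tries: int = 50) -> Tree:
    """One random SPR move that is guaranteed to change the unrooted
    topology (trivial reattachments are redrawn)."""
    before = bipartitions(tree)
    all_tips = tree.tip_labels()
    for _ in range(max_tries):
        edges = [
            n.tip_set()
            for n in tree.postorder()
            if n is not tree.root and len(all_tips - n.tip_set()) >= 3
        ]
        prune = edges[rng.integers(len(edges))]
        targets = [e for e in edges if not (e & prune)]
        if not targets:
            continue
        target = targets[rng.integers(len(targets))]
        try:
            candidate = spr(tree, prune, target)
        except Exception:
            continue
        if bipartitions(candidate) != before:
            return candidate
    raise RuntimeError("could not find a topology-changing SPR move")


def perturb_gene_trees(
    tree: Tree,
    n_trees: int,
    spr_moves: int,
    missing_frac: float,
    seed: int | np.random.Generator,
) -> list[Tree]:
    """Emulate single-marker gene trees: each output is the input tree after
    ``spr_moves`` random SPR rearrangements followed by random deletion of
    ``floor(missing_frac * n)`` tips."""
    if tree.n_tips() < 5:
        raise ValueError("need at least 5 tips to perturb")
    if not 0 <= missing_frac < 1:
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = tree.n_tips()
    n_drop = int(missing_frac * n)
    if n - n_drop < 4:
        raise ValueError(
            f"deleting {n_drop} of {n} tips leaves fewer than 4 taxa"
        )
    out = []
    for _ in range(n_trees):
        g = tree.copy()
        for _ in range(spr_moves):
            g = _random_spr(g, rng)
        if n_drop:
            labels = sorted(g.tip_labels())
            drop = rng.choice(len(labels), size=n_drop, replace=False)
            keep = [l for i, l in enumerate(labels) if i not in set(drop.tolist())]
            g = restrict_to(g, keep)
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# Ortholog tables
# ---------------------------------------------------------------------------

class OrthologTable:
    """Per-marker, per-taxon aligned sequences with paralogy flags.

    ``markers`` maps marker id -> {taxon -> aligned sequence}; a taxon
    absent from a marker is simply missing from the inner mapping.  Within a
    marker all sequences have equal aligned length.
    """

    def __init__(
        self,
        markers: dict[str, dict[str, str]],
        paralog_flags: set[str] | None = None,
        taxa: list[str] | None = None,
    ):
        for mid, seqs in markers.items():
            if len({len(s) for s in seqs.values()}) > 1:
                raise ValueError(f"unequal aligned lengths within marker {mid}")
        self.markers = dict(markers)
        self.paralog_flags = set(paralog_flags or ())
        if taxa is None:
            taxa = sorted({t for seqs in markers.values() for t in seqs})
        self.taxa = list(taxa)

    def marker_ids(self) -> list[str]:
        return sorted(self.markers)

    def marker_length(self, marker_id: str) -> int:
        seqs = self.markers[marker_id]
        return len(next(iter(seqs.values()))) if seqs else 0

    def absence_fraction(self, marker_id: str) -> float:
        present = sum(1 for t in self.taxa if t in self.markers[marker_id])
        return 1.0 - present / len(self.taxa)

    def missing_marker_count(self, taxon: str) -> int:
        return sum(1 for m in self.markers.values() if taxon not in m)

    def presence_frame(self):
        """Marker x taxon boolean presence table as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {t: [t in self.markers[m] for m in self.marker_ids()] for t in self.taxa},
            index=self.marker_ids(),
        )


def generate_ortholog_table(
    tree: Tree,
    n_markers: int,
    marker_length: int,
    missing_rate: float,
    paralog_markers: int = 0,
    seed: int | np.random.Generator = 0,
    model: SubstModel | None = None,
) -> OrthologTable:
    """Simulate a marker set: each marker is an alignment evolved on
    ``tree``, with taxa dropped independently at ``missing_rate``, and
    ``paralog_markers`` randomly chosen markers flagged as paralogous."""
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if paralog_markers > n_markers:
        raise ValueError("cannot flag more paralogous markers than markers")
    rng = np.random.default_rng(seed)
    if model is None:
        model = SubstModel.load("lg", alpha=0.7)
    width = max(3, len(str(n_markers)))
    ids = [f"m{i:0{width}d}" for i in range(1, n_markers + 1)]
    markers: dict[str, dict[str, str]] = {}
    for mid in ids:
        aln = simulate_alignment(tree, model, marker_length, rng)
        seqs = aln.to_dict()
        keep = {t: s for t, s in seqs.items() if rng.random() >= missing_rate}
        markers[mid] = keep
    flagged = rng.choice(ids, size=paralog_markers, replace=False) if paralog_markers else []
    return OrthologTable(markers, set(map(str, flagged)), taxa=sorted(tree.tip_labels()))


# ---------------------------------------------------------------------------
# The schematic Firmicutes fixture
# ---------------------------------------------------------------------------

FIXTURE_NEWICK = (
    "(Outgroup:0.4,((Halanaerobiales:0.25,Natranaerobiales:0.2):0.1,"
    "(Bacilli:0.2,(Clostridia_A:0.2,(Clostridia_B:0.2,"
    "(Peptococcaceae:0.15,Negativicutes:0.15):0.1):0.1):0.1):0.1):0.1);"
)

DIDERM = "diderm"
MONODERM = "monoderm"

CharacterMap = dict  # taxon label -> "diderm" | "monoderm"


def firmicutes_fixture() -> tuple[Tree, CharacterMap]:
    """The clade-level skeleton of the Firmicutes reference phylogeny, with
    cell-envelope states at the tips.

    Eight lineages: an outgroup (diderm), the deep-branching
    Halanaerobiales + Natranaerobiales pair, Bacilli, two non-Peptococcaceae
    clostridial clades, and Peptococcaceae with the Negativicutes as
    sister.  Outer membranes (diderm state) occur in the outgroup, the
    Halanaerobiales, and the Negativicutes only.  Branch lengths are
    plausible deep-phylogeny values chosen for simulation, not estimates.
    """
    tree = parse_newick(FIXTURE_NEWICK, rooted=True)
    chars = {
        "Outgroup": DIDERM,
        "Halanaerobiales": DIDERM,
        "Natranaerobiales": MONODERM,
        "Bacilli": MONODERM,
        "Clostridia_A": MONODERM,
        "Clostridia_B": MONODERM,
        "Peptococcaceae": MONODERM,
        "Negativicutes": DIDERM,
    }
    return tree, chars


def write_character_map(chars: CharacterMap, path) -> None:
    with open(path, "w") as fh:
        for taxon in sorted(chars):
            fh.write(f"{taxon}\t{chars[taxon]}\n")


def read_character_map(path) -> CharacterMap:
    chars = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            taxon, state = line.split("\t")
            state = state.strip()
            if state not in (DIDERM, MONODERM):
                raise ValueError(f"unknown envelope state {state!r} for {taxon}")
            chars[taxon] = state
    return chars


#: the gene labels of the emulated conserved outer-membrane locus: LPS
#: synthesis (lpx/kds), LPS transport (lpt/msbA), OMP assembly
#: (bamA/tamB/skp) and OM-peptidoglycan anchoring (ompM)
OM_LOCUS = (
    "lpxA", "lpxC", "lpxD", "lpxB", "kdsA", "kdsB", "msbA",
    "lptB", "lptFG", "lptAC", "bamA", "tamB", "skp", "ompM",
)


def generate_gene_orders(
    chars: CharacterMap,
    n_background: int = 80,
    seed: int | np.random.Generator = 0,
) -> list["object"]:
    """Synthetic gene orders for the synteny stage: every genome gets a
    shuffled background of shared housekeeping labels; genomes with the
    diderm state additionally carry the OM locus genes as one contiguous
    block (internal order shuffled) at a random position."""
    from .synteny import GeneOrder

    rng = np.random.default_rng(seed)
    background = [f"hk{i:03d}" for i in range(n_background)]
    orders = []
    for taxon in sorted(chars):
        genes = list(background)
        rng.shuffle(genes)
        if chars[taxon] == DIDERM:
            locus = list(OM_LOCUS)
            rng.shuffle(locus)
            pos = int(rng.integers(0, len(genes) + 1))
            genes[pos:pos] = locus
        orders.append(GeneOrder(taxon, genes))
    return orders


# ---------------------------------------------------------------------------
# Random trees (test scaffolding and null topologies)
# ---------------------------------------------------------------------------

def random_tree(
    labels: list[str],
    seed: int | np.random.Generator = 0,
    mean_length: float = 0.1,
) -> Tree:
    """A random binary topology over ``labels`` built by sequential random
    attachment, with exponential branch lengths."""
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    rng = np.random.default_rng(seed)

    def elen() -> float:
        return float(rng.exponential(mean_length))

    labels = list(labels)
    root = Node()
    a = root.add(Node(labels[0], elen()))
    b = root.add(Node(labels[1], elen()))
    edges = [a, b]
    for label in labels[2:]:
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        joint = Node()
        i = parent.children.index(target)
        parent.children[i] = joint
        joint.parent = parent
        joint.length = elen()
        target.parent = joint
        joint.children = [target]
        tip = joint.add(Node(label, elen()))
        edges.extend([joint, tip])
    t = Tree(root, rooted=False)
    return t.unrooted() if len(labels) >= 3 else t
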