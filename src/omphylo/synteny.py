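"""Conserved gene-cluster (synteny block) detection on gene-label orders.

The comparison that located the conserved outer-membrane locus shared by
the two diderm Firmicutes lineages is abstracted here to ordered lists of
gene labels (pre-computed orthogroup or function identifiers): a cluster
is a set of labels that occur co-localised - chainable with at most
``max_gap`` intervening genes between consecutive member hits - in enough
ingroup genomes, while being (co-localised-)absent from the outgroup.
Homology is by shared label; gene order *within* a block and strand are
not scored, so detection is invariant under reversal of any genome.

Detection proceeds pairwise: labels present in more than
``max_outgroup_frac`` of the outgroup are screened out first (housekeeping
background shared by all genomes cannot join a cluster); for every ingroup
genome pair the remaining shared labels are chained into windows -
contiguous stretches of hits with at most ``max_gap`` intervening genes
between consecutive hits - and window intersections of at least
``min_genes`` labels become candidate clusters; candidates are pooled,
screened against the coverage thresholds, and reduced to maximal label
sets.  Enumerating sub-windows (not only maximal chains) makes detection
exhaustive at pair level: a cluster is never lost because a longer, less
widely conserved chain engulfed it in one genome pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

__all__ = ["GeneOrder", "Cluster", "find_conserved_clusters", "read_gene_orders"]


@dataclass
class GeneOrder:
    """One genome's gene order: an id and the list of gene labels in
    chromosomal order (labels may repeat); strand is optional and unused
    by detection."""

    genome: str
    genes: list[str]
    strands: list[str] | None = None

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"genome {self.genome!r} has an empty gene list")


@dataclass
class Cluster:
    """A detected conserved cluster: its label set, where it occurs, and
    its ingroup/outgroup coverage fractions."""

    labels: frozenset[str]
    intervals: dict[str, tuple[int, int]]  # genome -> [start, end] positions
    ingroup_coverage: float
    outgroup_coverage: float

    @property
    def size(self) -> int:
        return len(self.labels)


def _runs(order: GeneOrder, labels: frozenset[str], max_gap: int):
    """Chain the occurrences of ``labels`` in one genome into maximal runs
    where consecutive hits have at most ``max_gap`` intervening genes;
    yields (label_set, start, end) per run."""
    hits = [(i, g) for i, g in enumerate(order.genes) if g in labels]
    run: list[tuple[int, str]] = []
    for pos, gene in hits:
        if run and pos - run[-1][0] > max_gap + 1:
            yield frozenset(g for _, g in run), run[0][0], run[-1][0]
            run = []
        run.append((pos, gene))
    if run:
        yield frozenset(g for _, g in run), run[0][0], run[-1][0]


def _windows(order: GeneOrder, labels: frozenset[str], max_gap: int):
    """Label sets of every chainable hit window (all contiguous sub-chains
    of the maximal runs)."""
    hits = [(i, g) for i, g in enumerate(order.genes) if g in labels]
    out = set()
    for a in range(len(hits)):
        window = {hits[a][1]}
        last = hits[a][0]
        for b in range(a + 1, len(hits)):
            if hits[b][0] - last > max_gap + 1:
                break
            window.add(hits[b][1])
            last = hits[b][0]
            out.add(frozenset(window))
    return out


def _covering_run(order: GeneOrder, labels: frozenset[str], max_gap: int):
    """The first run over ``labels`` containing every label, or None."""
    for run_labels, start, end in _runs(order, labels, max_gap):
        if run_labels >= labels:
            return (start, end)
    return None


def find_conserved_clusters(
    orders: list[GeneOrder],
    ingroup: set[str],
    outgroup: set[str],
    min_genes: int = 3,
    max_gap: int = 1,
    min_ingroup_frac: float = 1.0,
    max_outgroup_frac: float = 0.0,
) -> list[Cluster]:
    """Gene clusters co-localised across the ingroup and absent from the
    outgroup.

    A genome *covers* a candidate label set when all its labels occur in
    one run with at most ``max_gap`` intervening genes between consecutive
    member hits.  Emitted clusters cover at least ``min_ingroup_frac`` of
    the ingroup, at most ``max_outgroup_frac`` of the outgroup, have at
    least ``min_genes`` labels, and are maximal (no emitted cluster is a
    subset of another).  Output order: size descending, then label string.
    """
    ingroup = set(ingroup)
    outgroup = set(outgroup)
    if not ingroup:
        raise ValueError("empty ingroup")
    if ingroup & outgroup:
        raise ValueError("ingroup and outgroup overlap")
    if min_genes < 2:
        raise ValueError("min_genes must be at least 2")
    by_id = {o.genome: o for o in orders}
    missing = (ingroup | outgroup) - set(by_id)
    if missing:
        raise KeyError(f"no gene order for genome(s) {sorted(missing)}")

    # per-label outgroup screen: a label common in the outgroup can never
    # be part of an outgroup-absent cluster
    if outgroup:
        out_presence: dict[str, int] = {}
        for g in outgroup:
            for label in set(by_id[g].genes):
                out_presence[label] = out_presence.get(label, 0) + 1
        eligible = lambda lab: (
            out_presence.get(lab, 0) / len(outgroup) <= max_outgroup_frac
        )
    else:
        eligible = lambda lab: True

    candidates: set[frozenset[str]] = set()
    for ga, gb in combinations(sorted(ingroup), 2):
        a, b = by_id[ga], by_id[gb]
        shared = frozenset(
            lab for lab in frozenset(a.genes) & frozenset(b.genes)
            if eligible(lab)
        )
        if len(shared) < min_genes:
            continue
        windows_a = [w for w in _windows(a, shared, max_gap) if len(w) >= min_genes]
        windows_b = [w for w in _windows(b, shared, max_gap) if len(w) >= min_genes]
        for wa in windows_a:
            for wb in windows_b:
                inter = wa & wb
                if len(inter) >= min_genes:
                    candidates.add(inter)

    kept: list[Cluster] = []
    for labels in candidates:
        intervals = {}
        covered = 0
        for g in ingroup:
            run = _covering_run(by_id[g], labels, max_gap)
            if run is not None:
                intervals[g] = run
                covered += 1
        ingroup_cov = covered / len(ingroup)
        if ingroup_cov < min_ingroup_frac:
            continue
        out_covered = 0
        for g in outgroup:
            run = _covering_run(by_id[g], labels, max_gap)
            if run is not None:
                intervals[g] = run
                out_covered += 1
        outgroup_cov = out_covered / len(outgroup) if outgroup else 0.0
        if outgroup_cov > max_outgroup_frac:
            continue
        kept.append(Cluster(labels, intervals, ingroup_cov, outgroup_cov))

    # maximality: drop clusters whose label set is a strict subset of another
    maximal = [
        c
        for c in kept
        if not any(c.labels < other.labels for other in kept)
    ]
    maximal.sort(key=lambda c: (-c.size, ",".join(sorted(c.labels))))
    return maximal


def read_gene_orders(path) -> list[GeneOrder]:
    """Read a 3-column TSV (genome, position, label); positions define the
    order within each genome."""
    rows: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            genome, pos, label = line.rstrip("\n").split("\t")[:3]
            rows.setdefault(genome, []).append((int(pos), label))
    return [
        GeneOrder(genome, [g for _, g in sorted(entries)])
        for genome, entries in sorted(rows.items())
    ]


def clusters_table(clusters: list[Cluster]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "labels": ",".join(sorted(c.labels)),
                "n_genes": c.size,
                "ingroup_coverage": c.ingroup_coverage,
                "outgroup_coverage": c.outgroup_coverage,
            }
            for c in clusters
        ]
    )
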