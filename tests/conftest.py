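import numpy as np
import pytest

from omphylo.phylo_core import parse_newick
from omphylo.synthetic_data import SubstModel, firmicutes_fixture


@pytest.fixture(scope="session")
def lg():
    return SubstModel.load("lg", alpha=0.7)


@pytest.fixture(scope="session")
def poisson():
    return SubstModel.load("poisson", alpha=0.8)


@pytest.fixture()
def fixture_tree():
    tree, _ = firmicutes_fixture()
    return tree


@pytest.fixture()
def fixture_chars():
    _, chars = firmicutes_fixture()
    return chars


@pytest.fixture()
def quartet():
    return parse_newick("((A:0.3,B:0.5):0.2,(C:0.1,D:0.4):0.15);", rooted=True)


def brute_force_site_loglik(tree, aln, model):
    """Enumeration oracle: sum the joint probability over every assignment
    of internal-node states, averaged over the gamma categories."""
    import itertools

    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_tip]
    tips = [n for n in nodes if n.is_tip]
    rates = model.category_rates()
    out = np.zeros(aln.n_columns)
    seqs = {t: aln.row(t) for t in aln.taxa}
    for site in range(aln.n_columns):
        per_cat = []
        for r in rates:
            P = {
                id(n): model.transition_matrix((n.length or 0.0) * r)
                for n in nodes
                if n.parent is not None
            }
            total = 0.0
            for assign in itertools.product(range(20), repeat=len(internals)):
                st = {id(n): s for n, s in zip(internals, assign)}
                prob = model.freqs[st[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    code = None
                    if n.is_tip:
                        code = int(seqs[n.label][site])
                        if code >= 20:
                            continue  # ambiguous tip: sums to 1
                        prob *= P[id(n)][st[id(n.parent)], code]
                    else:
                        prob *= P[id(n)][st[id(n.parent)], st[id(n)]]
                total += prob
            per_cat.append(total)
        out[site] = np.log(np.mean(per_cat))
    return out
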