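"""Independent brute-force oracles for the cluster permutation machinery.

These deliberately avoid the package's own graph and t-statistic code
paths: components come from networkx, t values from scipy.stats.ttest_rel,
and permutation nulls from explicit enumeration of all label flips.
"""

import itertools

import networkx as nx
import numpy as np
from scipy import stats

from rifteeg import Montage


def toy_montage() -> Montage:
    """Six electrodes on a path A-B-C-D-E-F with a B-E chord."""
    names = ("A", "B", "C", "D", "E", "F")
    edges = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F"),
             ("B", "E")]
    return Montage(channel_names=names,
                   adjacency=frozenset(frozenset(e) for e in edges))


def nx_graph(montage: Montage) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(montage.channel_names)
    g.add_edges_from(tuple(p) for p in montage.adjacency)
    return g


def brute_force_clusters(tmap, montage, t_crit):
    """Same-sign significant components of size >= 2, as {frozenset: mass}."""
    g = nx_graph(montage)
    out = {}
    for sign in (+1, -1):
        nodes = [c for i, c in enumerate(montage.channel_names)
                 if abs(tmap[i]) > t_crit and np.sign(tmap[i]) == sign]
        for comp in nx.connected_components(g.subgraph(nodes)):
            if len(comp) >= 2:
                mass = sum(tmap[montage.index(c)] for c in comp)
                out[frozenset(comp)] = mass
    return out


def _max_mass(a, b, montage, t_crit):
    t = stats.ttest_rel(a, b, axis=0).statistic
    t = np.nan_to_num(t, nan=0.0)
    clusters = brute_force_clusters(t, montage, t_crit)
    return max((abs(m) for m in clusters.values()), default=0.0)


def exact_permutation_p(a, b, montage, alpha_form=0.05):
    """Exact per-cluster p by enumerating all 2**n paired label flips."""
    n = a.shape[0]
    t_crit = stats.t.ppf(1 - alpha_form / 2, n - 1)
    t_obs = stats.ttest_rel(a, b, axis=0).statistic
    observed = brute_force_clusters(np.nan_to_num(t_obs, nan=0.0),
                                    montage, t_crit)
    null = []
    for signs in itertools.product((1, -1), repeat=n):
        s = np.asarray(signs)[:, None]
        d = (a - b) * s
        null.append(_max_mass(b + d, b, montage, t_crit))
    null = np.asarray(null)
    return {comp: np.mean(null >= abs(mass))
            for comp, mass in observed.items()}
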