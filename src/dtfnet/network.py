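"""Graph-level summaries: degrees, edge scoring, assortative-mixing matrix E.

The common-source arithmetic is the motivating fact: a single generator
recorded at N electrodes yields N true source->sink links but up to
N(N-1)/2 spurious sink-sink links for any bivariate estimator — false links
grow as N^2 while true links grow as N.  ``classify_edges`` scores an
estimated adjacency against a known ground-truth network to measure exactly
that.

``mixing_matrix`` builds the module-by-module coupling matrix **E**: entry
E[k, l] aggregates the supra-threshold band-integrated connectivity from
source module l into target module k (row = target, column = source), then
the whole matrix is normalized to sum 1.  Diagonal dominance of **E**
("assortative mixing") means modules are internally strongly coupled and
communicate through weaker links.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .estimators import IntegratedConnectivity, PairMatrix
from .significance import Adjacency
from .simulate import GroundTruthNetwork

logger = logging.getLogger("dtfnet")

#: cap reported in place of an infinite intra/inter ratio
RATIO_CAP = 1e6


@dataclass
class ModulePartition:
    """Assignment of channel labels to named modules (total, non-overlapping)."""

    mapping: dict                   # label -> module id
    module_order: list = field(default_factory=list)

    def __post_init__(self):
        self.mapping = dict(self.mapping)
        if not self.module_order:
            seen = []
            for m in self.mapping.values():
                if m not in seen:
                    seen.append(m)
            self.module_order = seen
        if len(self.module_order) < 2:
            raise ValueError("need at least 2 modules")
        if set(self.mapping.values()) != set(self.module_order):
            raise ValueError("module_order must list exactly the assigned modules")

    @property
    def labels(self) -> list:
        return list(self.mapping)

    def members(self, module) -> list:
        return [lab for lab, m in self.mapping.items() if m == module]

    @classmethod
    def standard_1020(cls, pz_module: str = "PL") -> "ModulePartition":
        """Frontal / central / parietal-left / parietal-right 10-20 modules.

        The conventional grouping lists Pz in both parietal modules; a
        partition cannot overlap, so Pz goes to ``pz_module`` ("PL" by
        default, or "PR").
        """
        groups = {
            "F": ["Fp1", "Fp2", "Fpz", "F3", "F4", "Fz", "F7", "F8"],
            "C": ["C3", "Cz", "C4", "Cp5", "Cp6"],
            "PL": ["P7", "P3", "O1"],
            "PR": ["P8", "P4", "O2"],
        }
        if pz_module not in ("PL", "PR"):
            raise ValueError("pz_module must be 'PL' or 'PR'")
        groups[pz_module].insert(2, "Pz")
        mapping = {lab: mod for mod, labs in groups.items() for lab in labs}
        return cls(mapping, ["F", "C", "PL", "PR"])


@dataclass
class DegreeTable:
    """Per-channel degree counts."""

    table: pd.DataFrame
    directed: bool

    def __str__(self):
        return self.table.to_string()


@dataclass
class EdgeClassification:
    """Estimated edges scored against ground truth."""

    true_detected: list
    false_positives: list
    missed: list
    directed: bool

    @property
    def n_true_detected(self) -> int:
        return len(self.true_detected)

    @property
    def n_false_positives(self) -> int:
        return len(self.false_positives)

    @property
    def n_missed(self) -> int:
        return len(self.missed)

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, t, "true") for s, t in self.true_detected]
        rows += [(s, t, "false_positive") for s, t in self.false_positives]
        rows += [(s, t, "missed") for s, t in self.missed]
        return pd.DataFrame(rows, columns=["source", "target", "status"])


@dataclass
class MixingMatrix:
    """Module-by-module coupling matrix E; row = target module, column = source."""

    values: np.ndarray
    module_order: list
    normalized: bool
    estimator_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("E entries must be non-negative")
        if self.normalized and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("normalized E must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.module_order,
                            columns=self.module_order)


@dataclass
class AssortativityReport:
    """Per-module diagonal-vs-off-diagonal comparison of E."""

    table: pd.DataFrame
    assortative: bool

    def __str__(self):
        verdict = "assortative (modular)" if self.assortative else "not assortative"
        return f"{self.table.to_string()}\n=> {verdict}"


# ---------------------------------------------------------------------------

def node_degrees(adjacency: Adjacency) -> DegreeTable:
    """Out/in degree per channel (directed) or plain degree (undirected)."""
    labels = adjacency.channel_labels
    if adjacency.directed:
        g = nx.from_numpy_array(adjacency.matrix.T.astype(int),
                                create_using=nx.DiGraph)
        g = nx.relabel_nodes(g, dict(enumerate(labels)))
        df = pd.DataFrame({
            "out_degree": [g.out_degree(lab) for lab in labels],
            "in_degree": [g.in_degree(lab) for lab in labels],
        }, index=labels)
    else:
        g = nx.from_numpy_array(adjacency.matrix.astype(int))
        g = nx.relabel_nodes(g, dict(enumerate(labels)))
        df = pd.DataFrame({"degree": [g.degree(lab) for lab in labels]},
                          index=labels)
    df.index.name = "channel"
    return DegreeTable(df, adjacency.directed)


def classify_edges(adjacency: Adjacency, truth: GroundTruthNetwork,
                   respect_direction: bool = True) -> EdgeClassification:
    """Score estimated edges against ground truth.

    Direction-sensitive when the adjacency is directed and
    ``respect_direction`` is set; undirected estimators are matched against
    the undirected skeleton of the truth.  Conservation holds by
    construction: true_detected + missed = |truth edges|.
    """
    labels = set(adjacency.channel_labels)
    truth_labels = {lab for s, t, _, _ in truth.edges for lab in (s, t)}
    if not truth_labels <= labels:
        raise ValueError(
            f"truth mentions channels absent from the adjacency: "
            f"{sorted(truth_labels - labels)}")

    directed = adjacency.directed and respect_direction
    est = set()
    for src, tgt in adjacency.edge_list():
        est.add((src, tgt) if directed else frozenset((src, tgt)))
    if adjacency.directed and not respect_direction:
        est = {frozenset(e) if not isinstance(e, frozenset) else e for e in est}

    if directed:
        tru = truth.edge_set
        as_pair = lambda e: e
    else:
        tru = truth.undirected_edge_set
        as_pair = lambda e: tuple(sorted(e))

    detected = sorted(as_pair(e) for e in est & tru)
    false_pos = sorted(as_pair(e) for e in est - tru)
    missed = sorted(as_pair(e) for e in tru - est)
    return EdgeClassification(detected, false_pos, missed, directed)


def mixing_matrix(connectivity, partition: ModulePartition,
                  threshold: float = 0.05, agg: str = "sum",
                  normalize: bool = True) -> MixingMatrix:
    """Assortative-mixing matrix E from band-integrated connectivity.

    E[k, l] aggregates (default: sums) the connectivity values strictly above
    ``threshold`` over ordered channel pairs with the target in module k and
    the source in module l (self-pairs excluded), then the matrix is
    normalized so all entries sum to 1.  ``agg="mean"`` averages over the
    qualifying supra-threshold pairs instead (differs from the sum only by
    module-size factors).
    """
    if isinstance(connectivity, PairMatrix):
        m = connectivity.values
        labels = connectivity.channel_labels
        estimator = connectivity.estimator_id
    elif isinstance(connectivity, IntegratedConnectivity):
        m = connectivity.matrix
        labels = connectivity.channel_labels
        estimator = connectivity.estimator_id
    else:
        raise TypeError("expected IntegratedConnectivity or PairMatrix")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if set(labels) != set(partition.labels):
        raise ValueError("partition must cover exactly the connectivity channels")
    if agg not in ("sum", "mean"):
        raise ValueError("agg must be 'sum' or 'mean'")

    idx = {lab: i for i, lab in enumerate(labels)}
    modules = partition.module_order
    n_mod = len(modules)
    E = np.zeros((n_mod, n_mod))
    for a, tgt_mod in enumerate(modules):
        tgt = [idx[lab] for lab in partition.members(tgt_mod)]
        for b, src_mod in enumerate(modules):
            src = [idx[lab] for lab in partition.members(src_mod)]
            vals = [m[i, j] for i in tgt for j in src
                    if i != j and m[i, j] > threshold]
            if a == b and len(tgt) < 2:
                logger.warning("module %r has < 2 channels; E_kk set to 0",
                               tgt_mod)
                continue
            if vals:
                E[a, b] = np.sum(vals) if agg == "sum" else np.mean(vals)
    if normalize:
        total = E.sum()
        if total == 0:
            raise ValueError("no supra-threshold connections; E cannot be normalized")
        E = E / total
    return MixingMatrix(E, list(modules), normalize, estimator)


def assortativity_report(E: MixingMatrix) -> AssortativityReport:
    """Compare each module's intra-coupling E_kk with its inter-coupling.

    For module k the inter-coupling is the mean of the off-diagonal entries
    of row k and column k.  The global flag is true iff *every* module's
    diagonal entry exceeds its off-diagonal mean (diagonal dominance =
    assortative, modular organization).  Infinite ratios (zero inter-module
    coupling) are reported as the cap ``RATIO_CAP``.
    """
    if not E.normalized:
        raise ValueError("assortativity_report expects a normalized E")
    v = E.values
    n = len(E.module_order)
    rows = []
    for k in range(n):
        off = np.concatenate([np.delete(v[k], k), np.delete(v[:, k], k)])
        inter = float(off.mean()) if off.size else 0.0
        intra = float(v[k, k])
        if inter > 0:
            ratio = min(intra / inter, RATIO_CAP)
        else:
            ratio = RATIO_CAP if intra > 0 else 0.0
        rows.append((E.module_order[k], intra, inter, ratio, intra > inter))
    table = pd.DataFrame(rows, columns=["module", "intra", "inter_mean",
                                        "ratio", "assortative"]).set_index("module")
    return AssortativityReport(table, bool(table["assortative"].all()))
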