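"""Multipass reference likelihood pipeline with memory-transfer accounting.

The reference pipeline evaluates the same likelihood as the fused evaluator
but through five discrete stages per node, each materialising its results to a
simulated global store before the next stage re-reads them:

1. transform the transition block of each terminal child into a prelike table
   and write it to the store;
2. read the prelike tables / child conditional likelihoods back, compute the
   node's clp, write it to the store;
3. if the node's scalersSet flag is up, read the per-site lnScaler vector,
   remove the old stored scaler, write it back;
4. if the node is a scaler node, re-read the node's clp, find the per-site
   maximum, scale, write the clp and the updated lnScaler back;
5. at the root, read the root clp once more and combine site likelihoods.

Stage-2's prelike write/read round trip is the redundancy the fused design
removes.  Every store access is counted in a :class:`TransferLedger`, at the
granularity of whole objects: a clp access moves L residues of 16 floats, a
tip/prelike access 64 floats, an lnScaler access L floats.  Closed-form ledger
totals are available for the idealised accounting scenario — every down node
composed of one terminal and one internal child, every node a scaler node —
and :func:`verify_ledger` checks the instrumented pipelines against them cell
by cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CompressedAlignment
from .likelihood_fused import (FusedEvaluator, ImpossibleDataError, prelike,
                               _STATE_BITS)
from .subst_model import (GTRParams, build_rate_matrix, discrete_gamma_rates,
                          transition_block)
from .tree import Node, PhyloTree, caterpillar_tree

__all__ = [
    "TransferLedger",
    "MultipassEvaluator",
    "evaluate_multipass",
    "ledger_closed_form",
    "verify_ledger",
    "ScenarioError",
    "D_F", "D_CLP", "D_TIP",
]

# unit sizes in floats (d(f) = one float = 4 bytes in single precision)
D_F = 1
D_CLP = 16 * D_F   # one residue: 4 categories x 4 states
D_TIP = 64 * D_F   # one transition block: 4 categories x 4 x 4

PARAM_CLASSES = ("clp", "tip", "ls")
GROUPS = ("down", "root")


class ScenarioError(ValueError):
    """Raised when a tree does not fit the accounting scenario."""


@dataclass
class TransferLedger:
    """Counted reads/writes on the simulated global store.

    ``units[(cls, dir, group)]`` accumulates float-counts (d(f) units);
    ``events`` counts whole-object transfers (size-normalised to 1, the
    granularity of the O(...) complexity statements).  ``group`` separates
    down-node traffic from root traffic.  Per-node breakdowns are kept so unit
    costs for a single node of known composition can be read off.
    """

    units: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
    per_node: dict = field(default_factory=dict)
    _group: str = "down"
    _node: object = None

    def begin_node(self, node, group: str) -> None:
        self._group = group
        self._node = node

    def record(self, cls: str, direction: str, units: int) -> None:
        key = (cls, direction, self._group)
        self.units[key] = self.units.get(key, 0) + int(units)
        self.events[key] = self.events.get(key, 0) + 1
        if self._node is not None:
            node_units, node_events = self.per_node.setdefault(
                self._node, ({}, {}))
            k2 = (cls, direction)
            node_units[k2] = node_units.get(k2, 0) + int(units)
            node_events[k2] = node_events.get(k2, 0) + 1

    # -- queries ------------------------------------------------------------

    def cell(self, cls: str, direction: str, group: str) -> int:
        return self.units.get((cls, direction, group), 0)

    def total(self, cls: str, direction: str) -> int:
        return sum(self.cell(cls, direction, g) for g in GROUPS)

    def event_total(self, cls: str) -> int:
        return sum(self.events.get((cls, d, g), 0)
                   for d in ("r", "w") for g in GROUPS)

    def byte_total(self, cls: str, direction: str, d_f_bytes: int = 4) -> int:
        """Byte count at the stated float width (single precision by default)."""
        return self.total(cls, direction) * d_f_bytes

    def cells(self) -> dict:
        return {(cls, d, g): self.cell(cls, d, g)
                for cls in PARAM_CLASSES for d in ("r", "w") for g in GROUPS}

    def as_table(self) -> str:
        lines = ["class\tdir\tgroup\tunits_d(f)\ttransfers"]
        for cls in PARAM_CLASSES:
            for d in ("r", "w"):
                for g in GROUPS:
                    lines.append(f"{cls}\t{d}\t{g}\t{self.cell(cls, d, g)}"
                                 f"\t{self.events.get((cls, d, g), 0)}")
        return "\n".join(lines)


class _GlobalStore:
    """Simulated global memory: a keyed store whose accesses are counted."""

    def __init__(self, recorder: TransferLedger | None):
        self._data: dict = {}
        self._rec = recorder

    def write(self, key, value, cls: str, units: int):
        if self._rec is not None:
            self._rec.record(cls, "w", units)
        self._data[key] = value
        return value

    def read(self, key, cls: str, units: int):
        if self._rec is not None:
            self._rec.record(cls, "r", units)
        return self._data[key]


class MultipassEvaluator:
    """Five-stage reference evaluation of one tree likelihood.

    Stateless across calls: every :meth:`evaluate` is a cold start (lnScaler
    from zero, no stored scalers), so the value never depends on history.  A
    warm pass — the steady state of the accounting scenario, where every
    scaler node also carries an old scaler to remove — is available through
    ``evaluate(warm=True)``, which runs a silent cold pass first.

    ``tip_perturbation`` is a validation hook: it adds the given amount to one
    entry of the first terminal child's transition block, so that equivalence
    checks against the fused evaluator demonstrably fail when the pipelines
    diverge.
    """

    def __init__(self, tree: PhyloTree, data: CompressedAlignment, params: GTRParams,
                 scaler_policy="all", tip_perturbation: float = 0.0):
        if sorted(tree.taxon_labels) != sorted(data.taxon_labels):
            raise ValueError("tree and alignment taxon sets differ")
        self.tree = tree
        self.data = data
        self.params = params
        self.scaler_policy = scaler_policy
        self.tip_perturbation = tip_perturbation
        self._row_of_taxon = {lbl: i for i, lbl in enumerate(data.taxon_labels)}
        if scaler_policy == "all":
            self._is_scaler = lambda node: True
        elif scaler_policy == "none":
            self._is_scaler = lambda node: False
        elif callable(scaler_policy):
            self._is_scaler = scaler_policy
        else:
            raise ValueError(f"unknown scaler policy {scaler_policy!r}")

    def evaluate(self, recorder: TransferLedger | None = None,
                 warm: bool = False) -> float:
        """Run the five-stage pipeline; returns the total log-likelihood."""
        carry = None
        if warm:
            carry = self._pass(recorder=None, carry=None)[1]
        lnl, _ = self._pass(recorder=recorder, carry=carry)
        return lnl

    # carry = (stored per-node scalers, persisted lnScaler) of the last pass

    # -- pipeline ------------------------------------------------------------

    def _pass(self, recorder, carry):
        params = self.params
        rm = build_rate_matrix(params)
        rates = discrete_gamma_rates(params.alpha, params.n_cat)
        L = self.data.L
        store = _GlobalStore(recorder)
        old_scalers, ln_scaler = ({}, np.zeros(L)) if carry is None else carry
        # persisted lnScaler upload; initialisation, not a pipeline transfer
        store._data["ls"] = ln_scaler.copy()
        new_scalers = {}
        perturbed = [False]

        def tipblock(child: Node) -> np.ndarray:
            block = transition_block(rm, child.length, rates)
            if self.tip_perturbation and not perturbed[0] and child.is_leaf:
                block = block.copy()
                block[0, 0, 0] += self.tip_perturbation
                perturbed[0] = True
            return block

        def leaf_column(child: Node) -> np.ndarray:
            return self.data.patterns[
                self._row_of_taxon[self.tree.taxon_labels[child.taxon]]]

        root = self.tree.root
        for node in self.tree.internal_nodes():
            if recorder is not None:
                recorder.begin_node(node, "root" if node is root else "down")
            # kernel 1: prelike transform, materialised to the store
            for child in node.children:
                if child.is_leaf:
                    if recorder is not None:
                        recorder.record("tip", "r", D_TIP)
                    table = prelike(tipblock(child), np.unique(leaf_column(child)))
                    store.write(("prelike", id(child)), table, "tip", D_TIP)
            # kernel 2: clp from re-read prelike tables / child clps
            factor = np.ones((L, params.n_cat, 4))
            for child in node.children:
                if child.is_leaf:
                    table = store.read(("prelike", id(child)), "tip", D_TIP)
                    factor = factor * table[leaf_column(child)]
                else:
                    clp_child = store.read(("clp", id(child)), "clp", L * D_CLP)
                    block = tipblock(child)
                    factor = factor * np.matmul(
                        clp_child.transpose(1, 0, 2),
                        block.transpose(0, 2, 1)).transpose(1, 0, 2)
            clp = store.write(("clp", id(node)), factor, "clp", L * D_CLP)
            # kernel 3: remove the old scaler, if one is stored
            if id(node) in old_scalers:
                ls = store.read("ls", "ls", L * D_F)
                ls = ls - np.log(old_scalers[id(node)])
                store.write("ls", ls, "ls", L * D_F)
                ln_scaler = ls
            # kernel 4: new per-site scaler = max clp within each residue
            if self._is_scaler(node):
                clp = store.read(("clp", id(node)), "clp", L * D_CLP)
                scaler = clp.reshape(L, -1).max(axis=1)
                if np.any(scaler <= 0.0):
                    raise ImpossibleDataError("all conditional likelihoods zero")
                clp = clp / scaler[:, None, None]
                store.write(("clp", id(node)), clp, "clp", L * D_CLP)
                new_scalers[id(node)] = scaler
                ls = store.read("ls", "ls", L * D_F)
                ls = ls + np.log(scaler)
                store.write("ls", ls, "ls", L * D_F)
                ln_scaler = ls
        # kernel 5: root likelihood (invariable sites, frequencies, weights)
        clp_root = store.read(("clp", id(root)), "clp", L * D_CLP)
        lnl = self._combine(clp_root, ln_scaler)
        return lnl, (new_scalers, ln_scaler)

    def _combine(self, clp_root: np.ndarray, ln_scaler: np.ndarray) -> float:
        params = self.params
        pi = np.asarray(params.freqs)
        P = params.pinvar
        mix = (clp_root @ pi).mean(axis=1)
        meet = np.bitwise_and.reduce(self.data.patterns, axis=0).astype(int)
        inv = (_STATE_BITS @ pi)[meet]
        with np.errstate(divide="ignore"):
            term_var = ln_scaler + np.log((1.0 - P) * mix)
            if P > 0.0:
                ln_site = np.logaddexp(term_var, np.log(P * inv))
            else:
                ln_site = term_var
        if np.any(np.isneginf(ln_site)):
            warnings.warn("site with zero likelihood; reporting lnL = -inf",
                          RuntimeWarning)
            return float("-inf")
        return float(np.dot(self.data.weights.astype(float), ln_site))


def evaluate_multipass(tree: PhyloTree, data: CompressedAlignment,
                       params: GTRParams, scaler_policy="all",
                       warm: bool = False) -> tuple[float, TransferLedger]:
    """One-shot multipass log-likelihood plus its transfer ledger."""
    ledger = TransferLedger()
    lnl = MultipassEvaluator(tree, data, params, scaler_policy=scaler_policy
                             ).evaluate(recorder=ledger, warm=warm)
    return lnl, ledger


# ---------------------------------------------------------------------------
# closed forms (idealised accounting scenario)
# ---------------------------------------------------------------------------

def ledger_closed_form(scheme: str, N: int, L: int) -> TransferLedger:
    """Scenario ledger totals for ``multipass`` or ``fused``.

    Scenario: N-2 down nodes, each with one terminal and one internal child,
    plus a root of the same composition; every node is a scaler node carrying
    an old scaler (steady state).
    """
    if N < 3 or L < 1:
        raise ValueError("need N >= 3 and L >= 1")
    D = N - 2
    ledger = TransferLedger()

    def put(cls, d, group, units, events):
        ledger.units[(cls, d, group)] = units
        ledger.events[(cls, d, group)] = events

    if scheme == "multipass":
        put("clp", "w", "down", 2 * D * L * D_CLP, 2 * D)
        put("clp", "r", "down", 2 * D * L * D_CLP, 2 * D)
        put("tip", "w", "down", D * D_TIP, D)
        put("tip", "r", "down", 2 * D * D_TIP, 2 * D)
        put("ls", "w", "down", 2 * D * L * D_F, 2 * D)
        put("ls", "r", "down", 2 * D * L * D_F, 2 * D)
        put("clp", "w", "root", 2 * L * D_CLP, 2)
        put("clp", "r", "root", 3 * L * D_CLP, 3)
        put("tip", "w", "root", D_TIP, 1)
        put("tip", "r", "root", 2 * D_TIP, 2)
        put("ls", "w", "root", 2 * L * D_F, 2)
        put("ls", "r", "root", 2 * L * D_F, 2)
    elif scheme == "fused":
        put("clp", "w", "down", D * L * D_CLP, D)
        put("clp", "r", "down", D * L * D_CLP, D)
        put("tip", "w", "down", 0, 0)
        put("tip", "r", "down", D * D_TIP, D)
        put("ls", "w", "down", D * L * D_F, D)
        put("ls", "r", "down", D * L * D_F, D)
        put("clp", "w", "root", L * D_CLP, 1)
        put("clp", "r", "root", L * D_CLP, 1)
        put("tip", "w", "root", 0, 0)
        put("tip", "r", "root", D_TIP, 1)
        put("ls", "w", "root", L * D_F, 1)
        put("ls", "r", "root", L * D_F, 1)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return ledger


def clp_transfer_ratio(N: int) -> float:
    """Size-normalised clp transfer complexity ratio, multipass over fused."""
    return (4 * (N - 2) + 5) / (2 * (N - 2) + 2)


# ---------------------------------------------------------------------------
# measured-vs-closed-form verification
# ---------------------------------------------------------------------------

def _scenario_patterns(n_taxa: int, L: int, rng: np.random.Generator) -> CompressedAlignment:
    """Exactly L distinct unambiguous patterns over ``n_taxa`` taxa."""
    if 4 ** n_taxa < L:
        raise ScenarioError(f"cannot form {L} distinct patterns on {n_taxa} taxa")
    seen = set()
    cols = []
    states = np.array([1, 2, 4, 8], dtype=np.uint8)
    while len(cols) < L:
        col = tuple(rng.choice(states, size=n_taxa))
        if col not in seen:
            seen.add(col)
            cols.append(col)
    patterns = np.array(cols, dtype=np.uint8).T
    labels = [f"t{i}" for i in range(n_taxa)]
    return CompressedAlignment(labels, patterns, np.ones(L, dtype=np.int64),
                               np.arange(L))


def check_scenario_tree(tree: PhyloTree) -> None:
    """Require a binary-rooted caterpillar: the shape whose mid-chain down
    nodes and root realise the scenario's one-terminal + one-internal
    composition."""
    if len(tree.root.children) != 2:
        raise ScenarioError("scenario tree must have a binary root")
    for node in tree.down_nodes():
        leaf_children = sum(c.is_leaf for c in node.children)
        if leaf_children == 0:
            raise ScenarioError("scenario tree must be a caterpillar "
                                "(every down node has a terminal child)")


def _unit_costs(ledger: TransferLedger, tree: PhyloTree):
    """Per-node transfer costs for a scenario-composition down node and the
    root, read off the per-node breakdown of a measured ledger."""
    down_unit = None
    for node in tree.down_nodes():
        kinds = sorted(c.is_leaf for c in node.children)
        if kinds == [False, True]:
            down_unit = ledger.per_node[node]
            break
    if down_unit is None:
        raise ScenarioError("no down node with one terminal and one internal child")
    root_unit = ledger.per_node[tree.root]
    return down_unit, root_unit


def _scale_units(unit, factor: int) -> tuple[dict, dict]:
    node_units, node_events = unit
    return ({k: v * factor for k, v in node_units.items()},
            {k: v * factor for k, v in node_events.items()})


def measured_scenario_ledger(scheme: str, N: int, L: int,
                             seed: int = 20130409) -> TransferLedger:
    """Scenario ledger measured from an instrumented evaluation.

    Runs the instrumented pipeline warm (steady-state flags) on a real
    caterpillar, reads off the per-node unit costs of a down node and the root
    that realise the scenario composition, and scales by the scenario's node
    counts: (N-2) down nodes plus one root.  The extrapolation step exists
    because no finite binary tree realises the composition at its deepest
    node; the unit costs themselves are measured, not assumed.
    """
    if N < 3 or L < 1:
        raise ValueError("need N >= 3 and L >= 1")
    rng = np.random.default_rng(seed)
    m = max(N, 4)  # need at least one mid-chain down node to measure
    tree = caterpillar_tree(m)
    check_scenario_tree(tree)
    data = _scenario_patterns(m, L, rng)
    params = GTRParams((1.0, 2.0, 1.0, 1.0, 2.0, 1.0), (0.3, 0.2, 0.25, 0.25),
                       pinvar=0.1, alpha=0.7)
    ledger = TransferLedger()
    if scheme == "multipass":
        MultipassEvaluator(tree, data, params).evaluate(recorder=ledger, warm=True)
    elif scheme == "fused":
        ev = FusedEvaluator(tree, data, params)
        ev.evaluate()  # cold pass stores the scalers
        ev.propose_update(dirty_nodes=None, dirty_branches=None, recorder=ledger)
        ev.accept()
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    down_unit, root_unit = _unit_costs(ledger, tree)
    out = TransferLedger()
    d_units, d_events = _scale_units(down_unit, N - 2)
    r_units, r_events = _scale_units(root_unit, 1)
    for (cls, d), v in d_units.items():
        out.units[(cls, d, "down")] = v
    for (cls, d), v in d_events.items():
        out.events[(cls, d, "down")] = v
    for (cls, d), v in r_units.items():
        out.units[(cls, d, "root")] = v
    for (cls, d), v in r_events.items():
        out.events[(cls, d, "root")] = v
    return out


def verify_ledger(N: int, L: int, seed: int = 20130409) -> dict:
    """Compare measured scenario ledgers with the closed forms, cell by cell.

    Returns a report with per-cell matches for both schemes and the
    size-normalised clp transfer ratio check.
    """
    report = {"N": N, "L": L, "schemes": {}, "all_match": True}
    for scheme in ("multipass", "fused"):
        measured = measured_scenario_ledger(scheme, N, L, seed=seed)
        closed = ledger_closed_form(scheme, N, L)
        cells = {}
        for key, want in closed.cells().items():
            got = measured.cell(*key)
            cells[key] = {"measured": got, "closed_form": want,
                          "match": got == want}
            report["all_match"] &= (got == want)
        report["schemes"][scheme] = {
            "cells": cells,
            "clp_transfer_events": measured.event_total("clp"),
        }
    mp = report["schemes"]["multipass"]["clp_transfer_events"]
    fu = report["schemes"]["fused"]["clp_transfer_events"]
    report["clp_ratio_measured"] = mp / fu
    report["clp_ratio_closed_form"] = clp_transfer_ratio(N)
    report["clp_ratio_match"] = (mp == 4 * (N - 2) + 5) and (fu == 2 * (N - 2) + 2)
    report["all_match"] &= report["clp_ratio_match"]
    return report
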