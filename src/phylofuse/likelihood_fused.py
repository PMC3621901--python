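"""Fused single-pass likelihood evaluation under GTR+I+Gamma.

One pass over the postorder visits each internal node exactly once.  At a node
the evaluator (i) transforms the transition blocks of terminal children into
prelike lookup tables in-pass — never materialising them to a persistent
intermediate store, (ii) combines child contributions into the node's
conditional likelihoods (clp: L sites x n_cat categories x 4 states, 16 values
per site at 4 categories), and (iii) runs the per-site rescaling fused into the
same pass, with the scalersSet/scalerNode bit switches deferred until the
node's pass has completed.  Which of the 16 specialised down-node variants
handles a node is decided up front from its down_x class and scaler shortcut
T = 2S + N, so no per-site flag branching happens inside a pass.

Rescaling keeps clp in the linear domain: a scaler node divides each site's
16-value block by its maximum and accumulates the log in a per-site lnScaler;
a node whose scalersSet flag is up first removes the scaler it stored on a
previous visit, which makes re-evaluation after Metropolis proposals cheap and
exact.  The root combination corrects the invariable-site term by
exp(-lnScaler) so scaled and unscaled evaluations agree to round-off.

Two interchangeable data layouts evaluate the same arithmetic in different
orders: ``state_major`` computes each of the 16 per-site elements in its own
sweep across sites (many workers per residue), ``site_major`` computes whole
16-element blocks per site (one worker per residue); ``auto`` switches on the
number of unique sites.
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable

import numpy as np

from .io_formats import CompressedAlignment
from .subst_model import (GTRParams, RateMatrix, build_rate_matrix,
                          discrete_gamma_rates, transition_block)
from .tree import Node, PhyloTree, classify_node, shortcut, variant_id

__all__ = [
    "FusedEvaluator",
    "ImpossibleDataError",
    "prelike",
    "evaluate",
    "pruning_reference_loglikelihood",
    "brute_force_loglikelihood",
    "DEFAULT_LAYOUT_THRESHOLD",
]

#: Default unique-site count below which the auto layout picks state_major.
DEFAULT_LAYOUT_THRESHOLD = 512

_STATE_BITS = np.array([[(x >> s) & 1 for s in range(4)] for x in range(16)], dtype=float)


class ImpossibleDataError(ValueError):
    """All conditional likelihoods vanished at a site (scaler would be 0)."""


def prelike(block: np.ndarray, masks: Iterable[int]) -> np.ndarray:
    """Ambiguity-summed transition lookup for a terminal child.

    Returns a (16, n_cat, 4) table where entry ``[mask, r, m]`` is
    ``sum_{s in mask} P_r[m, s]``; only rows for the masks actually observed
    are filled.  A single-bit mask reproduces the tip column; mask 15 gives 1
    for every (category, parent state) because rows are stochastic.
    """
    block = np.asarray(block)
    table = np.zeros((16,) + block.shape[:-1], dtype=block.dtype)
    for mask in set(int(m) for m in masks):
        if mask == 0:
            raise ValueError("state mask 0 is not a legal observation")
        table[mask] = block @ _STATE_BITS[mask]
    return table


class FusedEvaluator:
    """Single-pass tree likelihood with cached per-node state.

    Parameters
    ----------
    tree : PhyloTree
        Tree whose leaf labels form a subset-equal match with ``data``.
    data : CompressedAlignment
        Pattern-compressed alignment.
    params : GTRParams
        Substitution-model parameters.
    layout : {"state_major", "site_major", "auto"}
        Evaluation order for the clp inner products.
    site_threshold : int
        With ``auto``, use state_major when L < threshold.
    scaler_policy : {"all", "none"} | int | callable
        Which internal nodes rescale: every one, none, every k-th in postorder,
        or a predicate.  Nodes created later (topology moves) default to the
        stateless policies' answer, or True under an integer policy.
    switch_mode : {"deferred", "immediate"}
        Whether scaler bit switches are committed after the node's pass
        (default, mirroring the fused architecture) or inside it; results are
        identical, the option exists to demonstrate that.
    dtype : numpy dtype
        float64 by default; float32 gives a single-precision parity mode.
    """

    def __init__(self, tree: PhyloTree, data: CompressedAlignment, params: GTRParams,
                 layout: str = "auto", site_threshold: int = DEFAULT_LAYOUT_THRESHOLD,
                 scaler_policy="all", switch_mode: str = "deferred",
                 dtype=np.float64):
        if layout not in ("state_major", "site_major", "auto"):
            raise ValueError(f"unknown layout {layout!r}")
        if switch_mode not in ("deferred", "immediate"):
            raise ValueError(f"unknown switch_mode {switch_mode!r}")
        if sorted(tree.taxon_labels) != sorted(data.taxon_labels):
            raise ValueError("tree and alignment taxon sets differ")
        self.tree = tree
        self.data = data
        self.layout = layout
        self.site_threshold = int(site_threshold)
        self.switch_mode = switch_mode
        self.dtype = dtype
        self._row_of_taxon = {lbl: i for i, lbl in enumerate(data.taxon_labels)}
        self._patterns = data.patterns
        self._weights = data.weights.astype(float)
        self.L = data.L
        self._set_scaler_policy(scaler_policy)
        self._variants = {(x, T): self._make_variant(x, T)
                          for x in range(4) for T in range(4)}
        # mutable evaluation state
        self._tipblocks: dict[Node, np.ndarray] = {}
        self._clp: dict[Node, np.ndarray] = {}
        self._node_scaler: dict[Node, np.ndarray] = {}
        self._ln_scaler = np.zeros(self.L, dtype=np.float64)
        self._pending: list[tuple[Node, bool]] = []
        self._snapshot = None
        self._recorder = None
        # states compatible with every taxon at each pattern (for the
        # invariable-site class); fixed by the data, weighted by the current pi
        self._meet = np.bitwise_and.reduce(self._patterns, axis=0).astype(int)
        self.set_params(params, _reset=True)

    # -- configuration ------------------------------------------------------

    def _set_scaler_policy(self, policy) -> None:
        self.scaler_policy = policy
        if policy == "all":
            self._is_scaler_node = lambda node: True
        elif policy == "none":
            self._is_scaler_node = lambda node: False
        elif isinstance(policy, int):
            chosen = set()
            for i, node in enumerate(self.tree.internal_nodes()):
                if i % policy == 0:
                    chosen.add(id(node))
            self._is_scaler_node = lambda node: id(node) in chosen or False
            self._every_k_chosen = chosen
        elif callable(policy):
            self._is_scaler_node = policy
        else:
            raise ValueError(f"unknown scaler policy {policy!r}")

    def set_params(self, params: GTRParams, scope: str = "full", _reset: bool = False) -> None:
        """Install new model parameters.

        ``scope='root_only'`` is valid when only pinvar changed: clps and
        transition blocks are untouched and only the root combination needs
        recomputing on the next update.
        """
        self.params = params
        if scope == "full" or _reset:
            qkey = (params.exch, params.freqs)
            if _reset or qkey != self._qkey:
                self._rate_matrix = build_rate_matrix(params)
                self._freqs = np.asarray(params.freqs)
                self._inv_pi = (_STATE_BITS @ self._freqs)[self._meet]
                self._qkey = qkey
            rkey = (params.alpha, params.n_cat)
            if _reset or rkey != self._rkey:
                self._rates = discrete_gamma_rates(params.alpha, params.n_cat)
                self._rkey = rkey
        elif scope != "root_only":
            raise ValueError(f"unknown scope {scope!r}")

    # -- one-shot evaluation -------------------------------------------------

    def evaluate(self, recorder=None) -> float:
        """Fresh full evaluation: clears all cached scaler state first."""
        self._tipblocks.clear()
        self._clp.clear()
        self._node_scaler.clear()
        self._ln_scaler[:] = 0.0
        for node in self.tree.postorder():
            node.scalers_set = False
        return self._run_pass(dirty=None, dirty_branches=None, recorder=recorder)

    # -- incremental evaluation (Metropolis proposals) ------------------------

    def propose_update(self, dirty_nodes=None, dirty_branches=(), removed_nodes=(),
                       recorder=None) -> float:
        """Re-evaluate after a proposal, recomputing only the dirty subtrees.

        ``dirty_nodes`` must be ancestor-closed (None means every internal
        node); ``dirty_branches`` are nodes whose branch length changed;
        ``removed_nodes`` are internal nodes detached by a topology move, whose
        stored scalers are lifted out of lnScaler.  A snapshot is taken so the
        proposal can be rolled back with :meth:`reject`.
        """
        if self._snapshot is not None:
            raise RuntimeError("previous proposal not yet accepted/rejected")
        snap_nodes = {}
        targets = (None if dirty_nodes is None else set(dirty_nodes) | set(removed_nodes))
        iter_nodes = (self.tree.internal_nodes() if targets is None
                      else [n for n in targets])
        for node in iter_nodes:
            snap_nodes[node] = (self._clp.get(node), self._node_scaler.get(node),
                                node.scalers_set)
        snap_branches = {node: self._tipblocks.get(node)
                         for node in (self._tipblocks if dirty_branches is None or targets is None
                                      else dirty_branches)}
        self._snapshot = (snap_nodes, dict(snap_branches), self._ln_scaler.copy(),
                          list(removed_nodes))
        for node in removed_nodes:
            sc = self._node_scaler.pop(node, None)
            if sc is not None:
                self._ln_scaler -= np.log(sc)
            node.scalers_set = False
            self._clp.pop(node, None)
        return self._run_pass(dirty=(None if dirty_nodes is None else set(dirty_nodes)),
                              dirty_branches=(None if dirty_branches is None
                                              else set(dirty_branches)),
                              recorder=recorder)

    def accept(self) -> None:
        if self._snapshot is None:
            raise RuntimeError("no pending proposal")
        snap_nodes, _, _, removed = self._snapshot
        for node in removed:
            self._clp.pop(node, None)
            self._node_scaler.pop(node, None)
            self._tipblocks.pop(node, None)
        self._snapshot = None

    def reject(self) -> None:
        if self._snapshot is None:
            raise RuntimeError("no pending proposal")
        snap_nodes, snap_branches, ln_scaler, _ = self._snapshot
        for node, (clp, scaler, sset) in snap_nodes.items():
            self._restore_entry(self._clp, node, clp)
            self._restore_entry(self._node_scaler, node, scaler)
            node.scalers_set = sset
        for node, block in snap_branches.items():
            self._restore_entry(self._tipblocks, node, block)
        self._ln_scaler = ln_scaler
        self._snapshot = None

    @staticmethod
    def _restore_entry(store: dict, key, value) -> None:
        if value is None:
            store.pop(key, None)
        else:
            store[key] = value

    # -- the pass -------------------------------------------------------------

    def _effective_layout(self) -> str:
        if self.layout != "auto":
            return self.layout
        return "state_major" if self.L < self.site_threshold else "site_major"

    def _tipblock(self, node: Node, dirty_branches, recorder=None) -> np.ndarray:
        block = self._tipblocks.get(node)
        if block is None or dirty_branches is None or node in dirty_branches:
            block = transition_block(self._rate_matrix, node.length, self._rates
                                     ).astype(self.dtype, copy=False)
            self._tipblocks[node] = block
        return block

    def _run_pass(self, dirty, dirty_branches, recorder=None) -> float:
        self._recorder = recorder
        internals = self.tree.internal_nodes()
        for node in internals:
            if dirty is not None and node not in dirty:
                continue
            if recorder is not None:
                recorder.begin_node(node, "root" if node is self.tree.root else "down")
            if node is self.tree.root:
                self._root_pass(node, dirty_branches)
            else:
                x = classify_node(node)
                S = 1 if node.scalers_set else 0
                N = 1 if self._is_scaler_node(node) else 0
                self._variants[(x, shortcut(S, N))](node, dirty_branches)
        lnl = self._combine_root()
        self._recorder = None
        self.last_loglik = lnl
        return lnl

    def _record(self, cls: str, direction: str, units: int) -> None:
        if self._recorder is not None:
            self._recorder.record(cls, direction, units)

    def _make_variant(self, x: int, T: int) -> Callable[[Node, object], None]:
        """Factory for one of the 16 down-node variants.

        ``x`` fixes which children are read through prelike tables vs child
        clp buffers; ``T`` bakes in the scaler steps.  T=0 variants contain no
        scaler code at all.
        """
        left_terminal = bool(x & 1)
        right_terminal = bool(x & 2)
        do_subtract = bool(T & 2)  # S bit
        do_rescale = bool(T & 1)   # N bit
        vid = variant_id(x, T)

        if T == 0:
            def variant(node: Node, dirty_branches) -> None:
                clp = self._node_clp(node, left_terminal, right_terminal, dirty_branches)
                self._clp[node] = clp
                self._record("clp", "w", self.L * 16)
        else:
            def variant(node: Node, dirty_branches) -> None:
                clp = self._node_clp(node, left_terminal, right_terminal, dirty_branches)
                self._scale_node(node, clp, do_subtract, do_rescale)
                self._clp[node] = clp
                self._record("clp", "w", self.L * 16)
                self._commit_switches(node)

        variant.variant_id = vid
        return variant

    def _node_clp(self, node: Node, left_terminal: bool, right_terminal: bool,
                  dirty_branches) -> np.ndarray:
        left, right = node.children
        if left.is_leaf != left_terminal or right.is_leaf != right_terminal:
            raise RuntimeError("node dispatched to the wrong down_x variant")
        return self._child_factor(left, dirty_branches) * self._child_factor(right, dirty_branches)

    def _child_factor(self, child: Node, dirty_branches) -> np.ndarray:
        block = self._tipblock(child, dirty_branches)
        if child.is_leaf:
            self._record("tip", "r", 64)
            col = self._patterns[self._row_of_taxon[self.tree.taxon_labels[child.taxon]]]
            table = prelike(block, np.unique(col))
            return table[col].astype(self.dtype, copy=False)
        self._record("clp", "r", self.L * 16)
        clp = self._clp[child]
        if self._effective_layout() == "state_major":
            out = np.empty_like(clp)
            n_cat = block.shape[0]
            for r in range(n_cat):
                for m in range(4):
                    out[:, r, m] = clp[:, r, :] @ block[r, m, :]
            return out
        # site-major: one batched product per category block
        return np.matmul(clp.transpose(1, 0, 2),
                         block.transpose(0, 2, 1)).transpose(1, 0, 2)

    def _scale_node(self, node: Node, clp: np.ndarray,
                    do_subtract: bool, do_rescale: bool) -> None:
        """Fused kernel-3/kernel-4 step, run inside the node's pass."""
        self._record("ls", "r", self.L)
        if do_subtract:
            old = self._node_scaler.pop(node)
            self._ln_scaler -= np.log(old)
            self._queue_switch(node, False)
        if do_rescale:
            scaler = clp.reshape(self.L, -1).max(axis=1)
            if np.any(scaler <= 0.0):
                bad = int(np.argmax(scaler <= 0.0))
                raise ImpossibleDataError(
                    f"all conditional likelihoods are zero at pattern {bad}")
            clp /= scaler[:, None, None]
            self._node_scaler[node] = scaler
            self._ln_scaler += np.log(scaler)
            self._queue_switch(node, True)
        self._record("ls", "w", self.L)

    def _queue_switch(self, node: Node, value: bool) -> None:
        if self.switch_mode == "immediate":
            node.scalers_set = value
        else:
            self._pending.append((node, value))

    def _commit_switches(self, node: Node) -> None:
        """Deferred bit switches: applied together once the pass is complete."""
        if self._pending:
            for n, value in self._pending:
                n.scalers_set = value
            self._pending.clear()

    def _root_pass(self, root: Node, dirty_branches) -> None:
        factor = self._child_factor(root.children[0], dirty_branches)
        for ch in root.children[1:]:
            factor = factor * self._child_factor(ch, dirty_branches)
        S = root.scalers_set
        N = self._is_scaler_node(root)
        if S or N:
            self._scale_node(root, factor, S, N)
        self._clp[root] = factor
        self._record("clp", "w", self.L * 16)
        self._commit_switches(root)

    def _combine_root(self) -> float:
        """Site-likelihood mixture at the root (the kernel-5 combination).

        lnL = sum_l w_l [ lnScaler_l + ln( (1-P)/n_cat sum_{r,m} pi_m clp_lrm
                                            + P inv_l exp(-lnScaler_l) ) ]
        evaluated through logaddexp so a large accumulated scaler cannot
        overflow the invariable-site correction.
        """
        clp_root = self._clp[self.tree.root]
        P = self.params.pinvar
        mix = clp_root.reshape(self.L, -1, 4) @ self._freqs
        mix = mix.mean(axis=1)  # (1/n_cat) sum_r
        with np.errstate(divide="ignore"):
            term_var = self._ln_scaler + np.log((1.0 - P) * mix)
            if P > 0.0:
                term_inv = np.log(P * self._inv_pi)
                ln_site = np.logaddexp(term_var, term_inv)
            else:
                ln_site = term_var
        if np.any(np.isneginf(ln_site)):
            warnings.warn("site with zero likelihood; reporting lnL = -inf "
                          "(likelihood 0)", RuntimeWarning)
            return float("-inf")
        return float(np.dot(self._weights, ln_site))


def evaluate(tree: PhyloTree, data: CompressedAlignment, params: GTRParams,
             layout: str = "auto", site_threshold: int = DEFAULT_LAYOUT_THRESHOLD,
             scaler_policy="all", recorder=None) -> float:
    """One-shot fused log-likelihood of ``tree`` given ``data`` and ``params``."""
    ev = FusedEvaluator(tree, data, params, layout=layout,
                        site_threshold=site_threshold, scaler_policy=scaler_policy)
    return ev.evaluate(recorder=recorder)


# ---------------------------------------------------------------------------
# independent references
# ---------------------------------------------------------------------------

def pruning_reference_loglikelihood(tree: PhyloTree, data: CompressedAlignment,
                                    params: GTRParams, dtype=np.float64) -> float:
    """Plain recursive pruning without any scaler machinery.

    Linear-domain partials: without rescaling they underflow to likelihood 0
    (lnL = -inf) on large trees — at the original hardware's single precision
    (``dtype=np.float32``) already at a couple of hundred taxa — which is
    exactly what the fused evaluator's per-site scalers prevent.
    """
    rm = build_rate_matrix(params)
    rates = discrete_gamma_rates(params.alpha, params.n_cat)
    row_of = {lbl: i for i, lbl in enumerate(data.taxon_labels)}
    L = data.L

    def partial(node: Node) -> np.ndarray:
        out = np.ones((L, params.n_cat, 4), dtype=dtype)
        for child in node.children:
            P = transition_block(rm, child.length, rates).astype(dtype)
            if child.is_leaf:
                col = data.patterns[row_of[tree.taxon_labels[child.taxon]]]
                table = prelike(P, np.unique(col))
                out *= table[col]
            else:
                out *= np.einsum("lrj,rmj->lrm", partial(child), P)
        return out

    clp_root = partial(tree.root)
    pi = np.asarray(params.freqs)
    mix = (clp_root @ pi).mean(axis=1)
    meet = np.bitwise_and.reduce(data.patterns, axis=0).astype(int)
    inv = (_STATE_BITS @ pi)[meet]
    site = (1.0 - params.pinvar) * mix + params.pinvar * inv
    if np.any(site <= 0.0):
        return float("-inf")
    return float(np.dot(data.weights, np.log(site)))


def brute_force_loglikelihood(tree: PhyloTree, data: CompressedAlignment,
                              params: GTRParams) -> float:
    """Exhaustive enumeration over all ancestral state assignments.

    Sums, for every site and rate category, the joint probability of every
    4^(number of internal nodes) assignment of states to internal nodes, with
    stationary weights at the root.  Exponential cost: a validation oracle for
    tiny trees only.
    """
    import itertools

    rm = build_rate_matrix(params)
    rates = discrete_gamma_rates(params.alpha, params.n_cat)
    row_of = {lbl: i for i, lbl in enumerate(data.taxon_labels)}
    internals = [n for n in tree.postorder() if not n.is_leaf]
    idx = {n: i for i, n in enumerate(internals)}
    pi = np.asarray(params.freqs)
    L = data.L
    mix = np.zeros(L)
    for r, rate in enumerate(rates):
        P = {n: transition_block(rm, n.length, np.array([rate]))[0]
             for n in tree.postorder() if n.parent is not None}
        total = np.zeros(L)
        for assign in itertools.product(range(4), repeat=len(internals)):
            prob = np.full(L, pi[assign[idx[tree.root]]])
            for node in internals:
                a = assign[idx[node]]
                for child in node.children:
                    if child.is_leaf:
                        col = data.patterns[row_of[tree.taxon_labels[child.taxon]]]
                        prob *= (P[child][a] * _STATE_BITS[col]).sum(axis=1)
                    else:
                        prob *= P[child][a, assign[idx[child]]]
            total += prob
        mix += total / len(rates)
    meet = np.bitwise_and.reduce(data.patterns, axis=0).astype(int)
    inv = (_STATE_BITS @ pi)[meet]
    site = (1.0 - params.pinvar) * mix + params.pinvar * inv
    return float(np.dot(data.weights, np.log(site)))
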