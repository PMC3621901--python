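"""Metropolis-coupled MCMC over trees and GTR+I+Gamma parameters.

A run couples one cold chain (heat beta = 1) with heated chains
(beta_i = 1 / (1 + lambda * i)); within each generation the chains are
advanced one by one, then one swap between a uniformly chosen chain pair is
attempted with acceptance min(1, (p_i / p_j)^(beta_j - beta_i)).  Only the
cold chain is sampled.  Two independent runs are performed by default and
compared through the average standard deviation of split frequencies (ASDSF).

Proposals: branch-length multiplier (log-uniform factor), NNI with a branch
multiplier, subtree prune-and-regraft with a uniform reinsertion point,
Dirichlet proposals on exchangeabilities and base frequencies, and reflected
sliding windows on the gamma shape and the invariable proportion.  A proposal
that lands outside its support raises the abort flag Q and is discarded
before any likelihood work.  Priors: flat Dirichlet on exchangeabilities and
frequencies, Exponential(10) branch lengths, Exponential(1) shape, Uniform(0,1)
invariable proportion.

Likelihood work is incremental: a proposal dirties only the ancestor chain of
what it touched, the evaluator re-runs those nodes (removing and re-adding
per-node scalers through the scalersSet machinery) and can roll the whole
update back on rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import dirichlet as _dirichlet

from .io_formats import Alignment, CompressedAlignment, compress_alignment
from .likelihood_fused import FusedEvaluator
from .reference_multipass import MultipassEvaluator
from .subst_model import GTRParams
from .simulate import random_tree
from .tree import BRLEN_FLOOR, Node, PhyloTree, swap_subtrees, _nni_choices

__all__ = [
    "RunConfig",
    "ProposalResult",
    "Chain",
    "Sample",
    "RunResult",
    "McmcResult",
    "propose",
    "mh_step",
    "swap_chains",
    "run_mc3",
    "split_frequencies",
    "asdsf",
    "log_prior",
    "credible_interval",
    "parameter_coverage",
    "write_run_files",
    "MOVE_NAMES",
]

BRLEN_MAX = 100.0
BRLEN_PRIOR_RATE = 10.0
ALPHA_PRIOR_RATE = 1.0
MULTIPLIER_TUNING = 2.0 * np.log(1.6)
DIRICHLET_CONC = 300.0
ALPHA_WINDOW = 0.5
PINVAR_WINDOW = 0.15

DEFAULT_START_PARAMS = GTRParams((1 / 6.0,) * 6, (0.25,) * 4,
                                 pinvar=0.1, alpha=1.0)

DEFAULT_MOVE_WEIGHTS = {
    "brlen_multiplier": 4.0,
    "nni": 3.0,
    "spr": 1.0,
    "exch_dirichlet": 1.0,
    "freq_dirichlet": 1.0,
    "alpha_window": 1.0,
    "pinvar_window": 1.0,
}
MOVE_NAMES = tuple(DEFAULT_MOVE_WEIGHTS)


@dataclass
class RunConfig:
    """Sampler configuration. Defaults follow the standard two-runs,
    four-chains (three heated) protocol with sampling and diagnosis every
    1000 generations."""

    n_generations: int
    n_runs: int = 2
    n_chains: int = 4
    heat_lambda: float = 0.1
    sample_freq: int = 1000
    diag_freq: int = 1000
    seed: int = 0
    burnin_frac: float = 0.25
    move_weights: dict = field(default_factory=lambda: dict(DEFAULT_MOVE_WEIGHTS))
    evaluator: str = "fused"          # "fused" | "multipass"
    scaler_policy: str | int = "all"
    layout: str = "auto"
    site_threshold: int = 512
    start_params: GTRParams = DEFAULT_START_PARAMS
    prior_only: bool = False
    min_split_freq: float = 0.1

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_runs < 1:
            raise ValueError("need at least one chain and one run")
        if self.sample_freq < 1 or self.diag_freq < 1:
            raise ValueError("frequencies must be positive")
        if not (0.0 <= self.burnin_frac < 1.0):
            raise ValueError("burn-in fraction must lie in [0, 1)")

    @property
    def n_heated(self) -> int:
        return self.n_chains - 1


@dataclass
class ProposalResult:
    """Outcome of one proposal: the state is already modified in place unless
    ``aborted`` (flag Q) is set; ``undo`` restores it exactly."""

    ln_hastings: float = 0.0
    aborted: bool = False
    undo: object = None
    dirty_nodes: object = None        # None = every internal node
    dirty_branches: object = None
    removed_nodes: tuple = ()
    new_params: GTRParams | None = None
    param_scope: str = "full"
    move: str = ""


def _ancestors_internal(node: Node | None) -> set[Node]:
    out: set[Node] = set()
    while node is not None:
        if not node.is_leaf:
            out.add(node)
        node = node.parent
    return out


def log_prior(tree: PhyloTree, params: GTRParams) -> float:
    """Log joint prior density (flat Dirichlets contribute constants only)."""
    total = 0.0
    n_edges = 0
    for node in tree.postorder():
        if node.parent is not None:
            total += node.length
            n_edges += 1
    lp = n_edges * np.log(BRLEN_PRIOR_RATE) - BRLEN_PRIOR_RATE * total
    lp += np.log(ALPHA_PRIOR_RATE) - ALPHA_PRIOR_RATE * params.alpha
    return float(lp)


# ---------------------------------------------------------------------------
# proposal moves
# ---------------------------------------------------------------------------

def _move_brlen_multiplier(chain: "Chain") -> ProposalResult:
    rng, tree = chain.rng, chain.tree
    edges = tree.edges()
    node = edges[rng.integers(len(edges))]
    c = float(np.exp(MULTIPLIER_TUNING * (rng.random() - 0.5)))
    new = node.length * c
    if not (BRLEN_FLOOR <= new <= BRLEN_MAX):
        return ProposalResult(aborted=True, move="brlen_multiplier")
    old = node.length
    node.length = new

    def undo() -> None:
        node.length = old

    return ProposalResult(ln_hastings=float(np.log(c)), undo=undo,
                          dirty_nodes=_ancestors_internal(node.parent),
                          dirty_branches={node}, move="brlen_multiplier")


def _move_nni(chain: "Chain") -> ProposalResult:
    rng, tree = chain.rng, chain.tree
    cands = [v for v in tree.internal_edges()
             if not (v.parent.parent is None and len(v.parent.children) == 2
                     and all(c.is_leaf for c in [s for s in v.parent.children
                                                 if s is not v]))]
    if not cands:
        return ProposalResult(aborted=True, move="nni")
    v = cands[rng.integers(len(cands))]
    a, b = _nni_choices(v)[rng.integers(2)]
    c = float(np.exp(MULTIPLIER_TUNING * (rng.random() - 0.5)))
    new_len = v.length * c
    if not (BRLEN_FLOOR <= new_len <= BRLEN_MAX):
        return ProposalResult(aborted=True, move="nni")
    old_len = v.length
    swap_subtrees(a, b)
    v.length = new_len

    def undo() -> None:
        swap_subtrees(a, b)
        v.length = old_len

    dirty = _ancestors_internal(a.parent) | _ancestors_internal(b.parent)
    return ProposalResult(ln_hastings=float(np.log(c)), undo=undo,
                          dirty_nodes=dirty, dirty_branches={v}, move="nni")


def _prunable(tree: PhyloTree) -> list[Node]:
    return [n for n in tree.postorder()
            if n.parent is not None and n.parent.parent is not None]


def _move_spr(chain: "Chain") -> ProposalResult:
    rng, tree = chain.rng, chain.tree
    prunable = _prunable(tree)
    if not prunable:
        return ProposalResult(aborted=True, move="spr")
    n = prunable[rng.integers(len(prunable))]
    p = n.parent
    g = p.parent
    c = next(ch for ch in p.children if ch is not n)
    n_prune_fwd = len(prunable)
    # detach: suppress p, merging its branch into the sibling's
    c_old_len = c.length
    g.replace_child(p, c)
    c.length = c_old_len + p.length
    targets = [e for e in tree.postorder() if e.parent is not None]
    t = targets[rng.integers(len(targets))]
    a = t.length
    s = rng.random() * a
    pt = t.parent
    q = Node(length=a - s)
    pt.replace_child(t, q)
    q.add_child(t)
    t.length = s
    q.add_child(n)
    n_prune_rev = len(_prunable(tree))

    def undo() -> None:
        pt.replace_child(q, t)
        t.length = a
        g.replace_child(c, p)
        c.parent = p
        c.length = c_old_len
        n.parent = p

    ln_h = (np.log(n_prune_fwd) + np.log(a)) - (np.log(n_prune_rev) + np.log(c.length))
    dirty = _ancestors_internal(g) | _ancestors_internal(q)
    return ProposalResult(ln_hastings=float(ln_h), undo=undo, dirty_nodes=dirty,
                          dirty_branches={c, t, q}, removed_nodes=(p,),
                          move="spr")


def _dirichlet_step(rng: np.random.Generator, x: np.ndarray
                    ) -> tuple[np.ndarray | None, float]:
    alpha_fwd = DIRICHLET_CONC * x
    new = rng.dirichlet(alpha_fwd)
    if np.any(new < 1e-5):
        return None, 0.0
    ln_h = (_dirichlet.logpdf(x, DIRICHLET_CONC * new)
            - _dirichlet.logpdf(new, alpha_fwd))
    return new, float(ln_h)


def _move_exch(chain: "Chain") -> ProposalResult:
    x = np.asarray(chain.params.exch)
    x = x / x.sum()
    new, ln_h = _dirichlet_step(chain.rng, x)
    if new is None:
        return ProposalResult(aborted=True, move="exch_dirichlet")
    return ProposalResult(ln_hastings=ln_h,
                          new_params=chain.params.replace(exch=tuple(new)),
                          move="exch_dirichlet")


def _move_freqs(chain: "Chain") -> ProposalResult:
    x = np.asarray(chain.params.freqs)
    new, ln_h = _dirichlet_step(chain.rng, x)
    if new is None:
        return ProposalResult(aborted=True, move="freq_dirichlet")
    new = new / new.sum()
    return ProposalResult(ln_hastings=ln_h,
                          new_params=chain.params.replace(freqs=tuple(new)),
                          move="freq_dirichlet")


def _move_alpha(chain: "Chain") -> ProposalResult:
    delta = chain.rng.uniform(-ALPHA_WINDOW, ALPHA_WINDOW)
    new = chain.params.alpha + delta
    if new < 0:
        new = -new  # reflect at 0
    if new == 0.0:
        return ProposalResult(aborted=True, move="alpha_window")
    return ProposalResult(new_params=chain.params.replace(alpha=float(new)),
                          move="alpha_window")


def _reflect_unit(x: float) -> float:
    while not (0.0 <= x < 1.0):
        if x < 0.0:
            x = -x
        elif x >= 1.0:
            x = 2.0 - x
        if x == 1.0:
            x = 1.0 - 1e-12
    return x


def _move_pinvar(chain: "Chain") -> ProposalResult:
    delta = chain.rng.uniform(-PINVAR_WINDOW, PINVAR_WINDOW)
    new = _reflect_unit(chain.params.pinvar + delta)
    return ProposalResult(new_params=chain.params.replace(pinvar=float(new)),
                          param_scope="root_only", dirty_nodes=frozenset(),
                          dirty_branches=frozenset(), move="pinvar_window")


_MOVES = {
    "brlen_multiplier": _move_brlen_multiplier,
    "nni": _move_nni,
    "spr": _move_spr,
    "exch_dirichlet": _move_exch,
    "freq_dirichlet": _move_freqs,
    "alpha_window": _move_alpha,
    "pinvar_window": _move_pinvar,
}


def propose(chain: "Chain", move_kind: str) -> ProposalResult:
    """Apply one proposal of the named kind to the chain state (in place).

    The returned result carries the Hastings ratio, the abort flag Q, the
    dirty sets for incremental re-evaluation, and an exact undo.
    """
    try:
        move = _MOVES[move_kind]
    except KeyError:
        raise ValueError(f"unknown move kind {move_kind!r}") from None
    return move(chain)


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

class _MultipassChainEvaluator:
    """Full-recompute adapter giving the multipass reference pipeline the
    incremental-evaluator interface. Every proposal re-evaluates the whole
    tree cold; rejection restores the cached value."""

    def __init__(self, tree, data, params, scaler_policy="all"):
        self.tree, self.data = tree, data
        self.params = params
        self.scaler_policy = "all" if scaler_policy not in ("all", "none") else scaler_policy
        self.last_loglik = None
        self._saved = None

    def _fresh(self) -> float:
        return MultipassEvaluator(self.tree, self.data, self.params,
                                  scaler_policy=self.scaler_policy).evaluate()

    def evaluate(self) -> float:
        self.last_loglik = self._fresh()
        return self.last_loglik

    def set_params(self, params, scope: str = "full") -> None:
        self.params = params

    def propose_update(self, dirty_nodes=None, dirty_branches=None,
                       removed_nodes=(), recorder=None) -> float:
        self._saved = self.last_loglik
        self.last_loglik = self._fresh()
        return self.last_loglik

    def accept(self) -> None:
        self._saved = None

    def reject(self) -> None:
        self.last_loglik = self._saved
        self._saved = None


class Chain:
    """One Markov chain: tree, parameters, heat, RNG stream and cached lnL."""

    def __init__(self, tree: PhyloTree, params: GTRParams,
                 data: CompressedAlignment | None, rng: np.random.Generator,
                 beta: float = 1.0, config: RunConfig | None = None,
                 heat_index: int = 0):
        self.tree = tree
        self.params = params
        self.rng = rng
        self.beta = beta
        self.heat_index = heat_index
        self.config = config or RunConfig(n_generations=0, n_runs=1, n_chains=1)
        self.use_data = data is not None and not self.config.prior_only
        if self.use_data:
            if self.config.evaluator == "fused":
                self.evaluator = FusedEvaluator(
                    tree, data, params, layout=self.config.layout,
                    site_threshold=self.config.site_threshold,
                    scaler_policy=self.config.scaler_policy)
            elif self.config.evaluator == "multipass":
                self.evaluator = _MultipassChainEvaluator(
                    tree, data, params, scaler_policy=self.config.scaler_policy)
            else:
                raise ValueError(f"unknown evaluator {self.config.evaluator!r}")
            self.ln_like = self.evaluator.evaluate()
        else:
            self.evaluator = None
            self.ln_like = 0.0
        self._weights = np.array([self.config.move_weights.get(m, 0.0)
                                  for m in MOVE_NAMES])
        self._weights = self._weights / self._weights.sum()
        self.n_proposed: dict[str, int] = {m: 0 for m in MOVE_NAMES}
        self.n_accepted: dict[str, int] = {m: 0 for m in MOVE_NAMES}
        self.n_aborted: dict[str, int] = {m: 0 for m in MOVE_NAMES}

    def log_prior(self) -> float:
        return log_prior(self.tree, self.params)

    def log_posterior(self) -> float:
        return self.ln_like + self.log_prior()

    def step(self, move_kind: str | None = None) -> bool:
        if move_kind is None:
            move_kind = MOVE_NAMES[self.rng.choice(len(MOVE_NAMES),
                                                   p=self._weights)]
        old_prior = self.log_prior()
        result = propose(self, move_kind)
        self.n_proposed[move_kind] += 1
        if result.aborted:
            self.n_aborted[move_kind] += 1
            if result.undo is not None:
                result.undo()
            return False
        accepted = mh_step(self, result, old_prior)
        if accepted:
            self.n_accepted[move_kind] += 1
        return accepted


def mh_step(chain: Chain, result: ProposalResult, old_prior: float | None = None) -> bool:
    """Metropolis–Hastings accept/reject for an applied (non-aborted) proposal.

    Acceptance probability min(1, (posterior ratio)^beta * Hastings ratio);
    commits or rolls back the chain state and its evaluator caches.
    """
    if result.aborted:
        raise ValueError("mh_step requires a non-aborted proposal")
    if old_prior is None:
        # state already modified: undo to measure, then reapply is not
        # possible generically, so callers normally pass old_prior in.
        raise ValueError("old_prior of the pre-proposal state is required")
    old_params = chain.params
    if result.new_params is not None:
        chain.params = result.new_params
        if chain.evaluator is not None:
            chain.evaluator.set_params(result.new_params, result.param_scope)
    if chain.evaluator is not None:
        new_like = chain.evaluator.propose_update(result.dirty_nodes,
                                                  result.dirty_branches,
                                                  result.removed_nodes)
    else:
        new_like = 0.0
    new_prior = chain.log_prior()
    ln_ratio = (chain.beta * ((new_like + new_prior)
                              - (chain.ln_like + old_prior))
                + result.ln_hastings)
    accept = (np.log(chain.rng.random()) < ln_ratio) if np.isfinite(ln_ratio) \
        else (ln_ratio > 0)
    if accept:
        if chain.evaluator is not None:
            chain.evaluator.accept()
        chain.ln_like = new_like
    else:
        if chain.evaluator is not None:
            chain.evaluator.reject()
        if result.undo is not None:
            result.undo()
        if result.new_params is not None:
            chain.params = old_params
            if chain.evaluator is not None:
                chain.evaluator.set_params(old_params, result.param_scope)
    return bool(accept)


def swap_chains(chains: list[Chain], rng: np.random.Generator) -> tuple[int, int, bool]:
    """Attempt one heat swap between a uniformly chosen chain pair.

    Accepted with probability min(1, (p_i / p_j)^(beta_j - beta_i)) where p is
    the (unheated) posterior kernel of each chain's current state.
    """
    if len(chains) < 2:
        return (0, 0, False)
    i, j = rng.choice(len(chains), size=2, replace=False)
    ci, cj = chains[i], chains[j]
    ln_ratio = (cj.beta - ci.beta) * (ci.log_posterior() - cj.log_posterior())
    accept = (np.log(rng.random()) < ln_ratio) if np.isfinite(ln_ratio) \
        else (ln_ratio > 0)
    if accept:
        ci.beta, cj.beta = cj.beta, ci.beta
        ci.heat_index, cj.heat_index = cj.heat_index, ci.heat_index
    return (int(i), int(j), bool(accept))


# ---------------------------------------------------------------------------
# runs
# ---------------------------------------------------------------------------

@dataclass
class Sample:
    gen: int
    ln_like: float
    newick: str
    splits: frozenset
    params: GTRParams
    tree_length: float
    mean_tip_length: float


@dataclass
class RunResult:
    samples: list
    taxon_labels: list
    acceptance: dict = field(default_factory=dict)

    def _after_burnin(self, burnin_frac: float) -> list:
        cut = int(np.floor(burnin_frac * len(self.samples)))
        return self.samples[cut:]

    def split_freqs(self, burnin_frac: float = 0.25) -> dict:
        return split_frequencies(self._after_burnin(burnin_frac), burnin_frac=0.0)

    def param_arrays(self, burnin_frac: float = 0.25) -> dict:
        kept = self._after_burnin(burnin_frac)
        out = {}
        for k in range(6):
            out[f"exch{k}"] = np.array(
                [np.asarray(s.params.exch)[k] / np.sum(s.params.exch)
                 for s in kept])
        for k, b in enumerate("ACGT"):
            out[f"pi_{b}"] = np.array([s.params.freqs[k] for s in kept])
        out["alpha"] = np.array([s.params.alpha for s in kept])
        out["pinvar"] = np.array([s.params.pinvar for s in kept])
        out["tree_length"] = np.array([s.tree_length for s in kept])
        out["mean_tip_length"] = np.array([s.mean_tip_length for s in kept])
        return out


@dataclass
class McmcResult:
    runs: list
    config: RunConfig
    asdsf_trace: list = field(default_factory=list)


class _Run:
    def __init__(self, data, config: RunConfig, run_seed, init_tree, labels):
        streams = run_seed.spawn(config.n_chains + 2)
        self.swap_rng = np.random.default_rng(streams[-1])
        init_rng = np.random.default_rng(streams[-2])
        self.chains: list[Chain] = []
        for i in range(config.n_chains):
            if init_tree is not None:
                tree, _ = init_tree.copy()
            else:
                tree = random_tree(len(labels), init_rng, labels=labels)
            beta = 1.0 / (1.0 + config.heat_lambda * i)
            self.chains.append(Chain(tree, config.start_params, data,
                                     np.random.default_rng(streams[i]),
                                     beta=beta, config=config, heat_index=i))
        self.n_swaps = 0
        self.n_swap_accepted = 0

    def cold_chain(self) -> Chain:
        return max(self.chains, key=lambda c: c.beta)

    def generation(self) -> None:
        for chain in self.chains:  # chains operated one by one
            chain.step()
        _, _, ok = swap_chains(self.chains, self.swap_rng)
        self.n_swaps += 1
        self.n_swap_accepted += int(ok)


def _take_sample(chain: Chain, gen: int) -> Sample:
    tree = chain.tree
    tips = [n.length for n in tree.postorder() if n.is_leaf]
    return Sample(gen=gen, ln_like=chain.ln_like, newick=tree.newick(),
                  splits=tree.splits(), params=chain.params,
                  tree_length=tree.total_length(),
                  mean_tip_length=float(np.mean(tips)))


def run_mc3(data, config: RunConfig, init_tree: PhyloTree | None = None) -> McmcResult:
    """Run the full Metropolis-coupled sampler: ``n_runs`` independent runs of
    coupled chains, sampling the cold chain and tracking ASDSF between the
    first two runs at every diagnosis point."""
    if isinstance(data, Alignment):
        data = compress_alignment(data)
    if data is not None and not isinstance(data, CompressedAlignment):
        raise TypeError("data must be an Alignment or CompressedAlignment")
    labels = data.taxon_labels if data is not None else (
        init_tree.taxon_labels if init_tree is not None else None)
    if labels is None:
        raise ValueError("need data or an initial tree to define the taxa")
    root_ss = np.random.SeedSequence(config.seed)
    runs = [_Run(data, config, rs, init_tree, labels)
            for rs in root_ss.spawn(config.n_runs)]
    results = [RunResult(samples=[], taxon_labels=list(labels)) for _ in runs]
    trace: list = []
    for run, res in zip(runs, results):
        res.samples.append(_take_sample(run.cold_chain(), 0))
    for gen in range(1, config.n_generations + 1):
        for run in runs:
            run.generation()
        if gen % config.sample_freq == 0:
            for run, res in zip(runs, results):
                res.samples.append(_take_sample(run.cold_chain(), gen))
        if gen % config.diag_freq == 0 and config.n_runs >= 2:
            f1 = results[0].split_freqs(config.burnin_frac)
            f2 = results[1].split_freqs(config.burnin_frac)
            try:
                trace.append((gen, asdsf(f1, f2, config.min_split_freq)))
            except ValueError:
                trace.append((gen, float("nan")))
    for run, res in zip(runs, results):
        res.acceptance = {
            "proposed": {m: sum(c.n_proposed[m] for c in run.chains)
                         for m in MOVE_NAMES},
            "accepted": {m: sum(c.n_accepted[m] for c in run.chains)
                         for m in MOVE_NAMES},
            "aborted": {m: sum(c.n_aborted[m] for c in run.chains)
                        for m in MOVE_NAMES},
            "swap_accept_rate": (run.n_swap_accepted / run.n_swaps
                                 if run.n_swaps else 0.0),
        }
    return McmcResult(runs=results, config=config, asdsf_trace=trace)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def split_frequencies(samples, burnin_frac: float = 0.25) -> dict:
    """Frequency of every non-trivial bipartition among sampled trees.

    ``samples`` may hold Sample objects, PhyloTree instances, or bare split
    sets; the leading ``burnin_frac`` fraction is discarded.
    """
    if not samples:
        raise ValueError("no samples")
    cut = int(np.floor(burnin_frac * len(samples)))
    kept = samples[cut:]
    counts: dict[int, int] = {}
    for s in kept:
        splits = (s.splits if isinstance(s, Sample)
                  else s.splits() if isinstance(s, PhyloTree) else s)
        for mask in splits:
            counts[mask] = counts.get(mask, 0) + 1
    return {mask: cnt / len(kept) for mask, cnt in counts.items()}


def asdsf(freqs1: dict, freqs2: dict, min_freq: float = 0.1) -> float:
    """Average standard deviation of split frequencies between two runs.

    Splits qualifying (frequency >= min_freq in at least one run) contribute
    the two-run sample standard deviation |f1 - f2| / sqrt(2).
    """
    qualifying = {m for m in set(freqs1) | set(freqs2)
                  if freqs1.get(m, 0.0) >= min_freq or freqs2.get(m, 0.0) >= min_freq}
    if not qualifying:
        raise ValueError("no splits at or above the reporting threshold")
    devs = [abs(freqs1.get(m, 0.0) - freqs2.get(m, 0.0)) / np.sqrt(2.0)
            for m in qualifying]
    return float(np.mean(devs))


def credible_interval(values: np.ndarray, level: float = 0.9) -> tuple[float, float]:
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(values, lo)), float(np.quantile(values, 1.0 - lo)))


def parameter_coverage(run: RunResult, truth_params: GTRParams,
                       truth_tree: PhyloTree, burnin_frac: float = 0.25,
                       level: float = 0.9) -> dict:
    """Which of the six free parameter groups' credible intervals cover truth.

    Groups: exchangeabilities (simplex-normalised, covered when >50% of the 6
    components are), base frequencies (>50% of 4), alpha, pinvar, total tree
    length, and mean terminal branch length.
    """
    arrays = run.param_arrays(burnin_frac)
    exch_truth = np.asarray(truth_params.exch) / np.sum(truth_params.exch)
    tips = [n.length for n in truth_tree.postorder() if n.is_leaf]
    scalars = {
        "alpha": truth_params.alpha,
        "pinvar": truth_params.pinvar,
        "tree_length": truth_tree.total_length(),
        "mean_tip_length": float(np.mean(tips)),
    }

    def covered(name: str, value: float) -> bool:
        lo, hi = credible_interval(arrays[name], level)
        return lo <= value <= hi

    out = {}
    exch_hits = sum(covered(f"exch{k}", exch_truth[k]) for k in range(6))
    out["exch"] = exch_hits > 3
    freq_hits = sum(covered(f"pi_{b}", truth_params.freqs[k])
                    for k, b in enumerate("ACGT"))
    out["freqs"] = freq_hits > 2
    for name, value in scalars.items():
        out[name] = covered(name, value)
    return out


# ---------------------------------------------------------------------------
# sample files
# ---------------------------------------------------------------------------

def write_run_files(result: RunResult, prefix: str) -> tuple[str, str]:
    """Write MrBayes-style sample files: ``<prefix>.t`` (one labelled newick
    per sampled generation) and ``<prefix>.p`` (tab-separated parameters)."""
    tpath, ppath = f"{prefix}.t", f"{prefix}.p"
    with open(tpath, "w") as fh:
        for s in result.samples:
            fh.write(f"tree gen_{s.gen} = {s.newick}\n")
    with open(ppath, "w") as fh:
        fh.write("Gen\tLnL\t" +
                 "\t".join(f"r({a}<->{b})" for a, b in
                           (("A", "C"), ("A", "G"), ("A", "T"),
                            ("C", "G"), ("C", "T"), ("G", "T"))) +
                 "\t" + "\t".join(f"pi({b})" for b in "ACGT") +
                 "\talpha\tpinvar\tTL\n")
        for s in result.samples:
            exch = np.asarray(s.params.exch) / np.sum(s.params.exch)
            row = ([f"{s.gen}", f"{s.ln_like:.6f}"]
                   + [f"{v:.6f}" for v in exch]
                   + [f"{v:.6f}" for v in s.params.freqs]
                   + [f"{s.params.alpha:.6f}", f"{s.params.pinvar:.6f}",
                      f"{s.tree_length:.6f}"])
            fh.write("\t".join(row) + "\n")
    return tpath, ppath
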