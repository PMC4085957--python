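"""Maximum-likelihood codon models of adaptive evolution.

The central object is :class:`CodonModel`, built from a codon alignment
and a labelled tree, whose :meth:`~CodonModel.fit` returns a
:class:`CodonModelResults` carrying estimates, log-likelihood, parameter
count, AIC and a ``summary()`` table.  Supported model families:

* ``M0``   one dN/dS ratio (omega) for all sites and branches;
* ``M1a``  nearly neutral: a purifying class (omega0 < 1) and a neutral
  class (omega = 1);
* ``M2a``  M1a plus a positive-selection class (omega2 >= 1) acting on
  all branches;
* ``modelA``  branch-site model A: omega2 >= 1 on a pre-specified set of
  *foreground* branches only, on a fraction of sites (classes 2a/2b);
  ``modelA_null`` is the same with omega2 fixed at 1.

Model comparison uses likelihood-ratio tests for nested pairs and AIC
(2k - 2 lnL) to rank non-nested foreground hypotheses, mirroring the
practice of screening several a-priori foreground sets and keeping the
one with the best AIC.

Branch lengths are estimated by coordinate ascent under M0 (per-branch
Brent updates on cached pruning messages, alternating with kappa/omega
updates) and then held fixed for the mixture models; pass
``branch_lengths="fixed"`` to use the input tree's lengths as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .alignment import CodonAlignment
from .genetics import GeneticCode, standard_code
from .likelihood import SiteClassMixture, TreePruner, codon_channel_set
from .ratematrix import (
    FREQUENCY_ESTIMATORS,
    CodonModelParams,
    SpectralMatrix,
    build_codon_rate_matrix,
)
from .tree import LabeledTree

KAPPA_BOUNDS = (0.01, 100.0)
OMEGA_FLOOR = 1e-4
OMEGA_CEIL = 50.0
_ALR_BOUND = 15.0

#: free parameters added by each model family on top of branch lengths,
#: frequency parameters and kappa
_EXTRA_FREE = {"M0": 1, "M1a": 2, "M2a": 4, "modelA": 4, "modelA_null": 3}


@dataclass(frozen=True)
class HypothesisSet:
    """A named a-priori foreground hypothesis.

    ``branches`` are individual branch ids; ``clades`` are named gene
    lineages whose entire subtree (stem included) becomes foreground.
    """

    name: str
    branches: tuple[str, ...] = ()
    clades: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.branches and not self.clades:
            raise ValueError(f"hypothesis {self.name!r} has no foreground branches")

    def apply(self, tree: LabeledTree) -> LabeledTree:
        return tree.with_foreground(branches=self.branches, clades=self.clades)

    def n_foreground(self, tree: LabeledTree) -> int:
        return int(self.apply(tree).foreground.sum())


class LRTResult(NamedTuple):
    statistic: float
    pvalue: float
    df: int


def likelihood_ratio_test(null_fit, alt_fit, df: int) -> LRTResult:
    """LRT of nested fits: 2(lnL_alt - lnL_null) against chi2(df).

    A negative difference (optimizer noise) is clamped to 0, giving p = 1.
    Accepts results objects (``.llf``) or bare log-likelihood floats.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    lnl0 = getattr(null_fit, "llf", null_fit)
    lnl1 = getattr(alt_fit, "llf", alt_fit)
    stat = max(0.0, 2.0 * (lnl1 - lnl0))
    return LRTResult(stat, float(chi2.sf(stat, df)) if stat > 0 else 1.0, df)


def aic_score(fit=None, *, llf: float | None = None, k: int | None = None) -> float:
    """Akaike information criterion, 2k - 2 lnL (lower is better)."""
    if fit is not None:
        llf = getattr(fit, "llf", None)
        k = getattr(fit, "k", None)
        if llf is None or k is None:
            llf, k = fit  # allow a plain (lnL, k) pair
    if llf is None or k is None:
        raise ValueError("need a fit or explicit llf and k")
    return 2.0 * k - 2.0 * llf


def foreground_site_fraction(fit) -> float:
    """Fraction of sites in the foreground classes of model A (p2a + p2b)."""
    if fit.model_tag not in ("modelA", "modelA_null"):
        raise ValueError(f"not a branch-site model A fit: {fit.model_tag}")
    p = fit.proportions
    return float(p["p2a"] + p["p2b"])


# -- results ------------------------------------------------------------


@dataclass
class CodonModelResults:
    """Fitted codon model: estimates, uncertainty-free point summary."""

    model_tag: str
    llf: float
    k: int
    kappa: float
    omegas: dict[str, float]
    proportions: dict[str, float]
    branch_lengths: dict[str, float]
    pi: np.ndarray = field(repr=False)
    mixture: SiteClassMixture = field(repr=False)
    foreground_set_name: str | None = None
    foreground_branches: tuple[str, ...] = ()
    converged: bool = True
    n_sites: int = 0
    n_taxa: int = 0
    seed: int | None = None

    @property
    def aic(self) -> float:
        return aic_score(llf=self.llf, k=self.k)

    @property
    def tree_length(self) -> float:
        return float(sum(self.branch_lengths.values()))

    def summary(self) -> str:
        lines = [
            f"Codon model {self.model_tag}",
            "=" * 58,
            f"No. taxa: {self.n_taxa:<6d} No. codon sites: {self.n_sites}",
            f"lnL: {self.llf:.4f}   k: {self.k}   AIC: {self.aic:.4f}",
            f"kappa (ts/tv): {self.kappa:.4f}   tree length: {self.tree_length:.4f}",
            "site classes (proportion | background omega | foreground omega):",
        ]
        for (prop, wb, wf), name in zip(
            self.mixture.classes, self.proportions.keys()
        ):
            lines.append(f"  {name:<4s} {prop:8.4f} | {wb:8.4f} | {wf:8.4f}")
        if self.foreground_set_name or self.foreground_branches:
            fg = ", ".join(self.foreground_branches)
            lines.append(
                f"foreground: {self.foreground_set_name or '(branches)'} [{fg}]"
            )
        lines.append(f"converged: {self.converged}")
        return "\n".join(lines)


#: alias: a fitted model is the "ModelFit" record of the analysis
ModelFit = CodonModelResults


# -- the model ----------------------------------------------------------


class CodonModel:
    """A codon substitution model bound to one alignment and tree.

    Parameters
    ----------
    alignment, tree
        The codon alignment and the phylogeny (alignment taxa must be a
        subset of the tree's leaves).
    model
        One of ``M0``, ``M1a``, ``M2a``, ``modelA``.
    foreground
        For ``modelA``: a :class:`HypothesisSet`, or an iterable of
        branch-id / clade-name strings (clade names expand to every branch
        of the lineage, stem included).  If omitted, the tree's own
        foreground flags are used.
    fix_omega2
        Fit the model A null (omega2 = 1) instead of the alternative.
    freq_model
        Codon frequency model: ``F3x4`` (default), ``F1x4`` or
        ``empirical``.
    branch_lengths
        ``"estimate"`` (default): optimise under M0, then hold fixed for
        mixture models; ``"fixed"``: use the input tree's lengths.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: LabeledTree,
        model: str = "M0",
        foreground: HypothesisSet | Iterable[str] | None = None,
        fix_omega2: bool = False,
        genetic_code: GeneticCode | None = None,
        freq_model: str = "F3x4",
        branch_lengths: str = "estimate",
    ):
        if model == "modelA" and fix_omega2:
            model_tag = "modelA_null"
        elif model in _EXTRA_FREE:
            model_tag = model
        else:
            raise ValueError(f"unknown model {model!r}")
        self.model_tag = model_tag
        self.alignment = alignment
        self.code = genetic_code or standard_code()
        if freq_model not in FREQUENCY_ESTIMATORS:
            raise ValueError(f"unknown frequency model {freq_model!r}")
        self.freq_model = freq_model
        estimator, self._n_freq_params = FREQUENCY_ESTIMATORS[freq_model]
        self.pi = estimator(alignment, self.code)
        if branch_lengths not in ("estimate", "fixed"):
            raise ValueError("branch_lengths must be 'estimate' or 'fixed'")
        self.branch_mode = branch_lengths

        self.foreground_set_name = None
        if isinstance(foreground, HypothesisSet):
            self.foreground_set_name = foreground.name
            tree = foreground.apply(tree)
        elif foreground is not None:
            names = list(foreground)
            if not names:
                raise ValueError("empty foreground set")
            clades = [n for n in names if n in tree.clades]
            branches = [n for n in names if n not in tree.clades]
            tree = tree.with_foreground(branches=branches, clades=clades)
        else:
            tree = tree.copy()
        if model_tag.startswith("modelA") and not tree.foreground.any():
            raise ValueError("branch-site model A needs a nonempty foreground set")
        self.tree = tree
        self._pruner = TreePruner(
            tree, alignment.state_matrix(self.code), list(alignment.ids), self.code.n_states
        )

    # -- likelihood plumbing --------------------------------------------

    def _loglik(self, mixture: SiteClassMixture, kappa: float, lengths: np.ndarray) -> float:
        work = self.tree
        work.lengths = lengths
        params = CodonModelParams(kappa, 1.0, self.pi)
        channels = codon_channel_set(work, mixture, params, self.code)
        return self._pruner.mixture_loglik(channels)

    def _k(self) -> int:
        return (
            self.tree.n_branches
            + self._n_freq_params
            + 1  # kappa
            + _EXTRA_FREE[self.model_tag]
        )

    # -- M0 with branch lengths -----------------------------------------

    def _fit_m0(
        self,
        lengths0: np.ndarray | None = None,
        kappa0: float = 2.0,
        omega0: float = 0.4,
        tol: float = 1e-3,
        max_rounds: int = 12,
    ):
        tree = self.tree
        if lengths0 is None:
            lengths0 = tree.lengths.copy()
            lengths0[lengths0 <= 0] = 0.05
            lengths0[tree.root] = 0.0
        lengths = lengths0.copy()
        kappa, omega = kappa0, omega0
        log_bounds = [
            (np.log(KAPPA_BOUNDS[0]), np.log(KAPPA_BOUNDS[1])),
            (np.log(OMEGA_FLOOR), np.log(OMEGA_CEIL)),
        ]
        prev = -np.inf
        converged = False
        for _ in range(max_rounds):
            # rate parameters given branch lengths
            res = minimize(
                lambda x: -self._loglik(
                    SiteClassMixture.m0(np.exp(x[1])), np.exp(x[0]), lengths
                ),
                np.log([kappa, omega]),
                method="L-BFGS-B",
                bounds=log_bounds,
                options={"maxiter": 60, "ftol": 1e-9},
            )
            kappa, omega = np.exp(res.x)
            # branch lengths given rate parameters, one Brent pass per edge
            sm = SpectralMatrix(
                build_codon_rate_matrix(
                    CodonModelParams(kappa, omega, self.pi), self.code
                ),
                self.pi,
            )
            lengths = self._branch_sweep(sm, lengths)
            cur = self._loglik(SiteClassMixture.m0(omega), kappa, lengths)
            if cur - prev < tol:
                converged = True
                prev = max(prev, cur)
                break
            prev = cur
        return kappa, omega, lengths, prev, converged

    def _branch_sweep(self, sm: SpectralMatrix, lengths: np.ndarray) -> np.ndarray:
        tree = self.tree
        pruner = self._pruner
        w = pruner.weights
        lengths = lengths.copy()
        P = sm.probabilities(lengths)
        down, dscale, G, gscale = pruner.messages(P, self.pi)
        order = [n for n in tree.postorder() if n != tree.root]
        for refresh, v in enumerate(order):
            if refresh and refresh % 6 == 0:
                # refresh messages periodically so later edges see updates
                P = sm.probabilities(lengths)
                down, dscale, G, gscale = pruner.messages(P, self.pi)
            const = dscale[v] + gscale[v]
            dv, gv = down[v], G[v]

            def neg(t: float) -> float:
                lik = (gv * (dv @ sm.probability(t).T)).sum(axis=1)
                return -float(w @ (np.log(np.maximum(lik, 1e-300)) + const))

            res = minimize_scalar(
                neg, bounds=(1e-8, 20.0), method="bounded",
                options={"xatol": 1e-6},
            )
            lengths[v] = res.x
        return lengths

    # -- mixture parameterisations --------------------------------------

    def _pack(self):
        """(build_mixture(theta), starts, bounds) for the model family."""
        tag = self.model_tag
        lb, ub = np.log(KAPPA_BOUNDS[0]), np.log(KAPPA_BOUNDS[1])
        kb = (lb, ub)
        w0b = (np.log(OMEGA_FLOOR), 0.0)
        w2b = (0.0, np.log(OMEGA_CEIL))
        ab = (-_ALR_BOUND, _ALR_BOUND)

        def sig(a):
            return 1.0 / (1.0 + np.exp(-a))

        def alr3(a0, a1):
            z = 1.0 + np.exp(a0) + np.exp(a1)
            return np.exp(a0) / z, np.exp(a1) / z

        if tag == "M0":
            return (
                lambda x: (np.exp(x[0]), SiteClassMixture.m0(np.exp(x[1]))),
                [np.log([2.0, 0.4]), np.log([1.2, 0.05])],
                [kb, (np.log(OMEGA_FLOOR), np.log(OMEGA_CEIL))],
            )
        if tag == "M1a":
            return (
                lambda x: (np.exp(x[0]), SiteClassMixture.m1a(sig(x[1]), np.exp(x[2]))),
                [
                    np.array([np.log(2.0), 1.0, np.log(0.15)]),
                    np.array([np.log(2.0), -1.0, np.log(0.5)]),
                ],
                [kb, ab, w0b],
            )
        if tag == "M2a":
            def build(x):
                p0, p1 = alr3(x[1], x[2])
                return np.exp(x[0]), SiteClassMixture.m2a(
                    p0, p1, np.exp(x[3]), np.exp(x[4])
                )

            starts = [
                np.array([np.log(2.0), 1.5, 0.5, np.log(0.15), np.log(1.5)]),
                np.array([np.log(2.0), 1.0, 1.0, np.log(0.3), np.log(3.0)]),
            ]
            return build, starts, [kb, ab, ab, w0b, w2b]
        if tag == "modelA":
            def build(x):
                p0, p1 = alr3(x[1], x[2])
                return np.exp(x[0]), SiteClassMixture.model_a(
                    p0, p1, np.exp(x[3]), np.exp(x[4])
                )

            starts = [
                np.array([np.log(2.0), 1.5, 0.5, np.log(0.15), np.log(1.5)]),
                np.array([np.log(2.0), 1.0, 0.0, np.log(0.3), np.log(3.0)]),
            ]
            return build, starts, [kb, ab, ab, w0b, w2b]
        # modelA_null: omega2 fixed at 1
        def build(x):
            p0, p1 = alr3(x[1], x[2])
            return np.exp(x[0]), SiteClassMixture.model_a(
                p0, p1, np.exp(x[3]), 1.0, null=True
            )

        starts = [
            np.array([np.log(2.0), 1.5, 0.5, np.log(0.15)]),
            np.array([np.log(2.0), 1.0, 0.0, np.log(0.3)]),
        ]
        return build, starts, [kb, ab, ab, w0b]

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        seed: int = 0,
        restarts: int = 1,
        start: np.ndarray | None = None,
        m0_result: CodonModelResults | None = None,
        warm_start: CodonModelResults | None = None,
        tol: float = 1e-3,
        maxiter: int = 200,
    ) -> CodonModelResults:
        """Maximise the likelihood; deterministic given ``seed``.

        ``m0_result`` supplies branch lengths (skipping the internal M0
        pass); ``warm_start`` seeds the optimiser from a nested fit (e.g.
        an M1a fit when fitting model A), which also guarantees the nested
        log-likelihood ordering up to optimiser tolerance.
        """
        rng = np.random.default_rng(seed)
        tree = self.tree

        if self.branch_mode == "fixed":
            lengths = tree.lengths.copy()
            m0_extra = None
        elif m0_result is not None:
            lengths = np.array(
                [
                    m0_result.branch_lengths.get(tree.branch_ids[i], 0.0)
                    for i in range(len(tree.parent))
                ]
            )
            m0_extra = (m0_result.kappa, m0_result.omegas.get("w", 0.4))
        else:
            kappa, omega, lengths, llf0, conv0 = self._fit_m0()
            m0_extra = (kappa, omega)
            if self.model_tag == "M0":
                return self._results(
                    kappa,
                    SiteClassMixture.m0(omega),
                    lengths,
                    llf0,
                    conv0,
                    seed,
                )

        build, starts, bounds = self._pack()
        if m0_extra is not None:
            for s in starts:
                s[0] = np.clip(np.log(m0_extra[0]), *bounds[0])
        if warm_start is not None:
            # the embedded nested optimum plus one exploratory start
            starts = [self._embed_warm_start(warm_start, bounds), starts[0]]
        if start is not None:
            starts = [np.asarray(start, dtype=float)] + starts
        for _ in range(max(0, restarts - 1)):
            base = starts[0].copy()
            jitter = rng.normal(0, 0.4, size=len(base))
            starts.append(np.clip(base + jitter, [b[0] for b in bounds], [b[1] for b in bounds]))

        def neg(x):
            kappa, mixture = build(x)
            return -self._loglik(mixture, kappa, lengths)

        best, any_success = None, False
        for x0 in starts:
            res = minimize(
                neg,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-9},
            )
            any_success = any_success or res.success
            if best is None or res.fun < best.fun:
                best = res
        converged = any_success or best.success
        if not converged:
            warnings.warn(
                f"{self.model_tag} optimisation did not fully converge: {best.message}",
                stacklevel=2,
            )
        kappa, mixture = build(best.x)
        return self._results(kappa, mixture, lengths, -best.fun, converged, seed)

    def _embed_warm_start(self, warm: CodonModelResults, bounds) -> np.ndarray:
        """Map a nested fit into this model's parameter vector."""
        lk = np.clip(np.log(warm.kappa), *bounds[0])
        props = warm.proportions
        w0 = warm.omegas.get("w0", 0.5 * min(1.0, warm.omegas.get("w", 0.5)))
        if self.model_tag == "M1a":
            p0 = np.clip(props.get("p0", 0.7), 1e-6, 1 - 1e-6)
            return np.array([lk, np.log(p0 / (1 - p0)), np.log(max(w0, OMEGA_FLOOR))])
        # M2a / modelA / modelA_null share the alr-pair layout
        p0 = max(props.get("p0", 0.6), 1e-6)
        p1 = max(props.get("p1", 1 - p0 - 1e-6), 1e-6)
        # push p2 to (almost) zero so the start reproduces the nested optimum
        scale = (1 - 1e-6) / (p0 + p1)
        p0, p1 = p0 * scale, p1 * scale
        p2 = max(1 - p0 - p1, 1e-7)
        a0 = np.clip(np.log(p0 / p2), -_ALR_BOUND, _ALR_BOUND)
        a1 = np.clip(np.log(p1 / p2), -_ALR_BOUND, _ALR_BOUND)
        vec = [lk, a0, a1, np.log(max(w0, OMEGA_FLOOR))]
        if self.model_tag in ("M2a", "modelA"):
            vec.append(np.log(max(warm.omegas.get("w2", 1.0 + 1e-4), 1.0 + 1e-6)))
        return np.array(vec)

    def _results(
        self,
        kappa: float,
        mixture: SiteClassMixture,
        lengths: np.ndarray,
        llf: float,
        converged: bool,
        seed: int,
    ) -> CodonModelResults:
        tree = self.tree
        tag = self.model_tag
        cls = mixture.classes
        if tag == "M0":
            omegas = {"w": cls[0][1]}
            props = {"p": 1.0}
        elif tag == "M1a":
            omegas = {"w0": cls[0][1], "w1": 1.0}
            props = {"p0": cls[0][0], "p1": cls[1][0]}
        elif tag == "M2a":
            omegas = {"w0": cls[0][1], "w1": 1.0, "w2": cls[2][1]}
            props = {"p0": cls[0][0], "p1": cls[1][0], "p2": cls[2][0]}
        else:
            omegas = {"w0": cls[0][1], "w1": 1.0, "w2": cls[2][2]}
            props = {
                "p0": cls[0][0],
                "p1": cls[1][0],
                "p2a": cls[2][0],
                "p2b": cls[3][0],
            }
        bl = {
            tree.branch_ids[i]: float(lengths[i])
            for i in range(len(tree.parent))
            if i != tree.root
        }
        return CodonModelResults(
            model_tag=tag,
            llf=float(llf),
            k=self._k(),
            kappa=float(kappa),
            omegas={k_: float(v) for k_, v in omegas.items()},
            proportions={k_: float(v) for k_, v in props.items()},
            branch_lengths=bl,
            pi=self.pi,
            mixture=mixture,
            foreground_set_name=self.foreground_set_name,
            foreground_branches=tuple(tree.foreground_branch_ids),
            converged=converged,
            n_sites=self.alignment.n_sites,
            n_taxa=self.alignment.n_taxa,
            seed=seed,
        )


# -- functional wrappers -------------------------------------------------


def fit_model(
    aln: CodonAlignment, tree: LabeledTree, model_tag: str, **opts
) -> CodonModelResults:
    """Fit a site model (M0, M1a or M2a) by maximum likelihood."""
    fit_opts = {
        k: opts.pop(k)
        for k in ("seed", "restarts", "start", "m0_result", "warm_start", "tol", "maxiter")
        if k in opts
    }
    return CodonModel(aln, tree, model=model_tag, **opts).fit(**fit_opts)


def fit_branch_site_A(
    aln: CodonAlignment,
    tree: LabeledTree,
    hyp: HypothesisSet | Iterable[str],
    fix_omega2: bool = False,
    **opts,
) -> CodonModelResults:
    """Fit branch-site model A for one foreground hypothesis."""
    fit_opts = {
        k: opts.pop(k)
        for k in ("seed", "restarts", "start", "m0_result", "warm_start", "tol", "maxiter")
        if k in opts
    }
    model = CodonModel(
        aln, tree, model="modelA", foreground=hyp, fix_omega2=fix_omega2, **opts
    )
    return model.fit(**fit_opts)


def rank_hypotheses(
    aln: CodonAlignment,
    tree: LabeledTree,
    hypotheses: Sequence[HypothesisSet],
    include_site_models: bool = True,
    seed: int = 0,
    decisive_delta: float = 10.0,
    **model_opts,
) -> pd.DataFrame:
    """Fit model A for every foreground hypothesis and rank all fits by AIC.

    Branch lengths are estimated once under M0 and shared by all model
    fits; each model-A fit is warm-started from the M1a optimum.  Returns
    a table sorted by ascending AIC (ties: fewer foreground branches,
    then name) with a Delta-AIC column and a decisiveness flag (Delta-AIC
    of the runner-up exceeding ``decisive_delta``).  Fitted results are
    attached in ``df.attrs["fits"]``.  A failing hypothesis is isolated:
    its row carries the error message and NaN scores.
    """
    if not hypotheses:
        raise ValueError("need at least one hypothesis")
    m0 = CodonModel(aln, tree, model="M0", **model_opts).fit(seed=seed)
    m1a = CodonModel(aln, tree, model="M1a", **model_opts).fit(seed=seed, m0_result=m0)
    rows, fits = [], {}

    def add(name, fg_name, n_fg, res, error=""):
        fits[name] = res
        rows.append(
            {
                "model": res.model_tag if res else name,
                "foreground": fg_name,
                "n_foreground": n_fg,
                "k": res.k if res else np.nan,
                "lnL": res.llf if res else np.nan,
                "AIC": res.aic if res else np.nan,
                "error": error,
            }
        )

    if include_site_models:
        add("M1a", "-", 0, m1a)
        m2a = CodonModel(aln, tree, model="M2a", **model_opts).fit(
            seed=seed, m0_result=m0, warm_start=m1a
        )
        add("M2a", "-", 0, m2a)
    for hyp in hypotheses:
        try:
            res = CodonModel(
                aln, tree, model="modelA", foreground=hyp, **model_opts
            ).fit(seed=seed, m0_result=m0, warm_start=m1a)
            add(f"modelA:{hyp.name}", hyp.name, hyp.n_foreground(tree), res)
        except Exception as exc:  # per-hypothesis failure isolation
            try:
                n_fg = hyp.n_foreground(tree)
            except Exception:
                n_fg = 0
            add(f"modelA:{hyp.name}", hyp.name, n_fg, None, str(exc))
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["AIC", "n_foreground", "foreground"], na_position="last"
    ).reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    ok = df["AIC"].notna()
    decisive = ok.sum() > 1 and df.loc[ok, "dAIC"].iloc[1] > decisive_delta
    df["decisive_best"] = [bool(decisive) and i == 0 for i in range(len(df))]
    df.attrs["fits"] = fits
    df.attrs["m0"] = m0
    return df
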