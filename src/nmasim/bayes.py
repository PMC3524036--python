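"""Bayesian hierarchical mixed-treatment-comparison models by MCMC.

Three models over arm-level binomial data with a logit link:

* **consistency MTC** — basic parameters d_AB, d_AC; the 2-3 contrast is
  the functional parameter d_BC = d_AC - d_AB.  Trial effects
  delta_k ~ Normal(d_bt, tau^2) in the random-effects flavor; tau^2 = 0
  gives the fixed-effect flavor.
* **random-inconsistency MTC** — as above, but the 2-3 contrast mean is
  d_BC = (d_AC - d_AB) + omega with omega ~ Normal(0, sigma_omega^2);
  the inconsistency factor omega is itself estimated.
* **inconsistency meta-analysis** — d_AB, d_AC, d_BC all free (no
  consistency constraint) with a shared tau^2; equivalent to three
  pairwise meta-analyses with pooled heterogeneity.  Node-splitting then
  contrasts its direct d_BC with the indirect d_AC - d_AB draw by draw.

Inference is a self-contained adaptive random-walk Metropolis-within-
Gibbs sampler: study baselines and trial effects are updated
element-wise (the likelihood factorizes over studies), pooled effects
and variance components as scalars, with per-component proposal scales
adapted toward 44% acceptance during burn-in.  Priors default to the
vague choices d, mu ~ Normal(0, 100^2), tau ~ Uniform(0, 2),
sigma_omega ~ Uniform(0, 2); all are configurable.

Default chain settings are 20,000 burn-in iterations, 40,000 sampling
iterations thinned 5:1 (8,000 retained draws per chain); shorter chains
for large replicated runs are passed explicitly through
:class:`MCMCSettings`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logit

from .scenarios import CONTRASTS
from .simulate import Trial, TrialNetwork

_CONTRAST_CODE = {(1, 2): 0, (1, 3): 1, (2, 3): 2}
_SIGNED_QUANTITIES = {"d_AB", "d_AC", "d_BC", "omega_BC"}
_TARGET_ACCEPT = 0.44  # optimal-ish for one-dimensional random-walk moves


@dataclass(frozen=True)
class PriorSpec:
    """Vague prior hyperparameters for the MTC models."""

    effect_prior_sd: float = 100.0
    tau_prior_upper: float = 2.0
    sigma_omega_prior_upper: float = 2.0

    def __post_init__(self) -> None:
        if min(self.effect_prior_sd, self.tau_prior_upper, self.sigma_omega_prior_upper) <= 0:
            raise ValueError("all prior hyperparameters must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    burn_in: int = 20000
    iterations: int = 40000
    thin: int = 5
    chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.iterations <= 0 or self.thin <= 0 or self.chains <= 0:
            raise ValueError("invalid MCMC settings")

    @property
    def n_kept(self) -> int:
        return self.iterations // self.thin


@dataclass(frozen=True)
class PosteriorSummary:
    """Moments, equal-tailed 95% interval and diagnostics of one quantity."""

    quantity: str
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    ess: float
    rhat: float
    significant: bool | None  # None for variance components

    def as_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ess": self.ess,
            "rhat": self.rhat,
            "significant": self.significant,
        }


class MTCData:
    """Arm-level data for a three-treatment network of two-arm trials.

    Each study contributes two arms; the base treatment of a study is
    the lower-numbered treatment present, and treatment 1 (the reference
    A) anchors the basic parameters.
    """

    def __init__(
        self,
        base_treat: np.ndarray,
        other_treat: np.ndarray,
        events_base: np.ndarray,
        n_base: np.ndarray,
        events_other: np.ndarray,
        n_other: np.ndarray,
        study_ids: list[str] | None = None,
    ) -> None:
        self.base_treat = np.asarray(base_treat, dtype=int)
        self.other_treat = np.asarray(other_treat, dtype=int)
        self.events_base = np.asarray(events_base, dtype=float)
        self.n_base = np.asarray(n_base, dtype=float)
        self.events_other = np.asarray(events_other, dtype=float)
        self.n_other = np.asarray(n_other, dtype=float)
        self.study_ids = study_ids or [f"s{i}" for i in range(len(self.base_treat))]
        if not (self.base_treat < self.other_treat).all():
            raise ValueError("base treatment must be the lower-numbered one")
        pairs = set(zip(self.base_treat.tolist(), self.other_treat.tolist()))
        if not pairs <= set(CONTRASTS):
            raise ValueError(f"treatments must form contrasts among {CONTRASTS}")
        self.contrast_code = np.array(
            [_CONTRAST_CODE[(b, t)] for b, t in zip(self.base_treat, self.other_treat)]
        )

    @property
    def n_studies(self) -> int:
        return len(self.base_treat)

    def contrasts_present(self) -> set[tuple[int, int]]:
        return set(zip(self.base_treat.tolist(), self.other_treat.tolist()))

    def is_connected(self) -> bool:
        """True when the treatments present form a single connected graph."""
        present = self.contrasts_present()
        nodes = {t for pair in present for t in pair}
        if not nodes:
            return False
        seen = {min(nodes)}
        frontier = [min(nodes)]
        while frontier:
            u = frontier.pop()
            for a, b in present:
                for v in ((b,) if a == u else (a,) if b == u else ()):
                    if v not in seen:
                        seen.add(v)
                        frontier.append(v)
        return seen == nodes

    @classmethod
    def from_trials(cls, trials: list[Trial]) -> "MTCData":
        return cls(
            base_treat=[t.contrast[0] for t in trials],
            other_treat=[t.contrast[1] for t in trials],
            events_base=[t.events_ctrl for t in trials],
            n_base=[t.n_ctrl for t in trials],
            events_other=[t.events_trt for t in trials],
            n_other=[t.n_trt for t in trials],
            study_ids=[t.study_id for t in trials],
        )

    @classmethod
    def from_network(cls, network: TrialNetwork) -> "MTCData":
        return cls.from_trials(list(network.trials))


@dataclass
class MTCFit:
    """Posterior summaries plus the retained draws of one model fit."""

    kind: str  # "consistency" | "ribmtc" | "ibma"
    model: str  # "fixed" | "random"
    summaries: dict[str, PosteriorSummary]
    draws: dict[str, np.ndarray]  # each (chains, n_kept)
    settings: MCMCSettings
    priors: PriorSpec

    def summary(self, quantity: str) -> PosteriorSummary:
        return self.summaries[quantity]


# ---------------------------------------------------------------------------
# Sampler internals


def _loglik(r: np.ndarray, n: np.ndarray, eta) -> np.ndarray:
    # binomial log likelihood with logit link, dropping the constant term
    return r * eta - n * np.logaddexp(0.0, eta)


def _run_chain(
    data: MTCData,
    kind: str,
    random_effects: bool,
    priors: PriorSpec,
    settings: MCMCSettings,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    K = data.n_studies
    con = data.contrast_code
    rb, nb = data.events_base, data.n_base
    rt, nt = data.events_other, data.n_other
    sd2 = priors.effect_prior_sd**2
    is_ab = con == 0
    is_ac = con == 1
    is_bc = con == 2

    # Empirical-logit initial values keep early iterations in a sane region.
    mu = np.asarray(logit((rb + 0.5) / (nb + 1.0)), dtype=float)
    y = np.asarray(logit((rt + 0.5) / (nt + 1.0)), dtype=float) - mu

    def _cmean(mask: np.ndarray) -> float:
        return float(y[mask].mean()) if mask.any() else 0.0

    st = {"d_AB": _cmean(is_ab), "d_AC": _cmean(is_ac)}
    if kind == "ibma":
        st["d_BC"] = _cmean(is_bc)
    if kind == "ribmtc":
        st["omega"] = 0.0
        # initial values must lie inside the uniform prior's support
        st["sigma"] = min(0.5, 0.5 * priors.sigma_omega_prior_upper)
    if random_effects:
        st["tau"] = min(0.2, 0.5 * priors.tau_prior_upper)
    delta = y.copy() if random_effects else None

    def mean_vec() -> np.ndarray:
        if kind == "ibma":
            bc = st["d_BC"]
        else:
            bc = st["d_AC"] - st["d_AB"]
            if kind == "ribmtc":
                bc = bc + st["omega"]
        return np.where(is_ab, st["d_AB"], np.where(is_ac, st["d_AC"], bc))

    effect_names = ["d_AB", "d_AC"]
    if kind == "ibma":
        effect_names.append("d_BC")
    if kind == "ribmtc":
        effect_names.append("omega")

    # d(mean_k)/d(effect) for each study: used by the joint translation
    # move that shifts an effect and its dependent trial effects together.
    if kind == "ibma":
        effect_coef = {
            "d_AB": np.where(is_ab, 1.0, 0.0),
            "d_AC": np.where(is_ac, 1.0, 0.0),
            "d_BC": np.where(is_bc, 1.0, 0.0),
        }
    else:
        effect_coef = {
            "d_AB": np.where(is_ab, 1.0, np.where(is_bc, -1.0, 0.0)),
            "d_AC": np.where(is_ac, 1.0, np.where(is_bc, 1.0, 0.0)),
        }
        if kind == "ribmtc":
            effect_coef["omega"] = np.where(is_bc, 1.0, 0.0)

    def scalar_logtarget(name: str) -> float:
        m = mean_vec()
        if random_effects:
            ll = -0.5 * float(np.sum((delta - m) ** 2)) / st["tau"] ** 2
        else:
            ll = float(np.sum(_loglik(rt, nt, mu + m)))
        v = st[name]
        if name == "omega":
            return ll - 0.5 * v**2 / st["sigma"] ** 2
        return ll - 0.5 * v**2 / sd2

    # Adaptive proposal scales (log scale), per component.
    log_s_mu = np.full(K, math.log(0.3))
    log_s_de = np.full(K, math.log(0.3))
    log_s = {name: math.log(0.2) for name in effect_names}
    log_s.update({f"joint_{name}": math.log(0.1) for name in effect_names})
    if random_effects:
        log_s["tau"] = math.log(0.1)
    if kind == "ribmtc":
        log_s["sigma"] = math.log(0.3)
    acc_mu = np.zeros(K)
    acc_de = np.zeros(K)
    acc = dict.fromkeys(log_s, 0.0)

    n_total = settings.burn_in + settings.iterations
    kept = {name: np.empty(settings.n_kept) for name in
            ("d_AB", "d_AC", "d_BC") + (("tau2",) if random_effects else ())
            + (("omega_BC", "sigma_omega2") if kind == "ribmtc" else ())}
    kept_i = 0
    batch = 50  # adaptation window during burn-in

    for it in range(n_total):
        # --- study baselines mu_k (element-wise Metropolis)
        m = mean_vec()
        off = delta if random_effects else m
        prop = mu + np.exp(log_s_mu) * rng.standard_normal(K)
        logr = (
            _loglik(rb, nb, prop)
            - _loglik(rb, nb, mu)
            + _loglik(rt, nt, prop + off)
            - _loglik(rt, nt, mu + off)
            + 0.5 * (mu**2 - prop**2) / sd2
        )
        ok = np.log(rng.random(K)) < logr
        mu = np.where(ok, prop, mu)
        acc_mu += ok

        # --- trial effects delta_k (random-effects flavor only)
        if random_effects:
            tau2 = st["tau"] ** 2
            prop = delta + np.exp(log_s_de) * rng.standard_normal(K)
            logr = (
                _loglik(rt, nt, mu + prop)
                - _loglik(rt, nt, mu + delta)
                - 0.5 * ((prop - m) ** 2 - (delta - m) ** 2) / tau2
            )
            ok = np.log(rng.random(K)) < logr
            delta = np.where(ok, prop, delta)
            acc_de += ok

        # --- pooled effects (and omega)
        for name in effect_names:
            cur_lp = scalar_logtarget(name)
            cur = st[name]
            st[name] = cur + math.exp(log_s[name]) * rng.standard_normal()
            if math.log(rng.random()) < scalar_logtarget(name) - cur_lp:
                acc[name] += 1.0
            else:
                st[name] = cur

        # --- joint translation moves along the slow-mixing ridge.  In the
        # random-effects flavor, shift an effect and the delta of every
        # dependent study together (random-effects terms invariant; only
        # the binomial likelihood of shifted arms and the effect's prior
        # change).  In the fixed flavor, shift the effect and compensate
        # the dependent studies' baselines by half, the least-informative
        # direction of the mu-d ridge.
        for name in effect_names:
            coef = effect_coef[name]
            eps = math.exp(log_s[f"joint_{name}"]) * rng.standard_normal()
            cur = st[name]
            new = cur + eps
            if name == "omega":
                dprior = -0.5 * (new**2 - cur**2) / st["sigma"] ** 2
            else:
                dprior = -0.5 * (new**2 - cur**2) / sd2
            if random_effects:
                shift = coef * eps
                dll = float(
                    np.sum(_loglik(rt, nt, mu + delta + shift))
                    - np.sum(_loglik(rt, nt, mu + delta))
                )
                if math.log(rng.random()) < dll + dprior:
                    st[name] = new
                    delta = delta + shift
                    acc[f"joint_{name}"] += 1.0
            else:
                m = mean_vec()
                prop_mu = mu - 0.5 * coef * eps
                dll = float(
                    np.sum(_loglik(rb, nb, prop_mu) - _loglik(rb, nb, mu))
                    + np.sum(
                        _loglik(rt, nt, prop_mu + m + coef * eps)
                        - _loglik(rt, nt, mu + m)
                    )
                )
                dprior += -0.5 * float(np.sum(prop_mu**2 - mu**2)) / sd2
                if math.log(rng.random()) < dll + dprior:
                    st[name] = new
                    mu = prop_mu
                    acc[f"joint_{name}"] += 1.0

        # --- between-study sd tau (uniform prior on tau)
        if random_effects:
            m = mean_vec()
            ss = float(np.sum((delta - m) ** 2))

            def tau_lp(t: float) -> float:
                return -K * math.log(t) - 0.5 * ss / t**2

            cur = st["tau"]
            prop_t = cur + math.exp(log_s["tau"]) * rng.standard_normal()
            if 1e-8 < prop_t <= priors.tau_prior_upper and math.log(
                rng.random()
            ) < tau_lp(prop_t) - tau_lp(cur):
                st["tau"] = prop_t
                acc["tau"] += 1.0

        # --- inconsistency sd sigma_omega (uniform prior on sigma)
        if kind == "ribmtc":
            om = st["omega"]

            def sig_lp(s: float) -> float:
                return -math.log(s) - 0.5 * om**2 / s**2

            cur = st["sigma"]
            prop_s = cur + math.exp(log_s["sigma"]) * rng.standard_normal()
            if 1e-8 < prop_s <= priors.sigma_omega_prior_upper and math.log(
                rng.random()
            ) < sig_lp(prop_s) - sig_lp(cur):
                st["sigma"] = prop_s
                acc["sigma"] += 1.0

        # --- adaptation during burn-in
        if it < settings.burn_in and (it + 1) % batch == 0:
            step = min(0.1, (it // batch + 1) ** -0.5)
            log_s_mu += np.where(acc_mu / batch > _TARGET_ACCEPT, step, -step)
            acc_mu[:] = 0.0
            if random_effects:
                log_s_de += np.where(acc_de / batch > _TARGET_ACCEPT, step, -step)
                acc_de[:] = 0.0
            for name in log_s:
                log_s[name] += step if acc[name] / batch > _TARGET_ACCEPT else -step
                acc[name] = 0.0

        # --- retain
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            kept["d_AB"][kept_i] = st["d_AB"]
            kept["d_AC"][kept_i] = st["d_AC"]
            if kind == "ibma":
                kept["d_BC"][kept_i] = st["d_BC"]
            elif kind == "ribmtc":
                kept["d_BC"][kept_i] = st["d_AC"] - st["d_AB"] + st["omega"]
                kept["omega_BC"][kept_i] = st["omega"]
                kept["sigma_omega2"][kept_i] = st["sigma"] ** 2
            else:
                kept["d_BC"][kept_i] = st["d_AC"] - st["d_AB"]
            if random_effects:
                kept["tau2"][kept_i] = st["tau"] ** 2
            kept_i += 1

    return kept


def _split_rhat(x: np.ndarray) -> float:
    """Plain split-R-hat over chains split in half (not rank-normalized)."""
    c, n = x.shape
    h = n // 2
    if h < 2:
        return float("nan")
    parts = x[:, : 2 * h].reshape(c * 2, h)
    w = float(parts.var(axis=1, ddof=1).mean())
    b = float(h * parts.mean(axis=1).var(ddof=1))
    if w <= 0:
        return 1.0
    return math.sqrt((h - 1) / h + b / (w * h))


def _ess(x: np.ndarray) -> float:
    try:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(az.ess(np.asarray(x)))
    except Exception:  # pragma: no cover - diagnostic fallback
        return float("nan")


def _summarize(draws: dict[str, np.ndarray]) -> dict[str, PosteriorSummary]:
    out = {}
    for name, x in draws.items():
        flat = x.reshape(-1)
        lo, hi = np.quantile(flat, [0.025, 0.975])
        significant = (not lo <= 0.0 <= hi) if name in _SIGNED_QUANTITIES else None
        out[name] = PosteriorSummary(
            quantity=name,
            mean=float(flat.mean()),
            sd=float(flat.std(ddof=1)),
            ci_low=float(lo),
            ci_high=float(hi),
            ess=_ess(x),
            rhat=_split_rhat(x),
            significant=significant,
        )
    return out


def _fit(
    data: MTCData,
    kind: str,
    priors: PriorSpec | None,
    settings: MCMCSettings | None,
    model: str,
    check_ess: bool = True,
) -> MTCFit:
    priors = priors or PriorSpec()
    settings = settings or MCMCSettings()
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    if data.n_studies == 0:
        raise ValueError("empty network")
    if not data.is_connected():
        raise ValueError("network must be connected")
    if 1 not in set(data.base_treat.tolist()):
        raise ValueError("reference treatment 1 (A) must be present")
    if kind in ("ribmtc", "ibma") and data.contrasts_present() != set(CONTRASTS):
        raise ValueError(f"{kind} requires all three contrasts (a closed loop)")

    chains = []
    for ch in range(settings.chains):
        ss = np.random.SeedSequence(entropy=settings.seed, spawn_key=(ch,))
        chains.append(
            _run_chain(data, kind, model == "random", priors, settings, np.random.default_rng(ss))
        )
    draws = {
        name: np.stack([c[name] for c in chains]) for name in chains[0]
    }
    summaries = _summarize(draws)
    if check_ess:
        poor = [
            s.quantity
            for s in summaries.values()
            if (np.isfinite(s.ess) and s.ess < 100 * settings.chains)
            or (np.isfinite(s.rhat) and s.rhat > 1.05)
        ]
        if poor:
            warnings.warn(
                f"possible non-convergence (low ESS or high R-hat) for: {poor}",
                RuntimeWarning,
                stacklevel=3,
            )
    return MTCFit(kind, model, summaries, draws, settings, priors)


# ---------------------------------------------------------------------------
# Public model fits


def fit_consistency_bmtc(
    data: MTCData,
    priors: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
    model: str = "random",
    check_ess: bool = True,
) -> MTCFit:
    """Consistency Bayesian MTC: d_BC constrained to d_AC - d_AB."""
    return _fit(data, "consistency", priors, settings, model, check_ess)


def fit_random_inconsistency_bmtc(
    data: MTCData,
    priors: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
    model: str = "random",
    check_ess: bool = True,
) -> MTCFit:
    """Random-inconsistency MTC: d_BC = d_AC - d_AB + omega, omega ~ N(0, sigma^2)."""
    return _fit(data, "ribmtc", priors, settings, model, check_ess)


def fit_ibma(
    data: MTCData,
    priors: PriorSpec | None = None,
    settings: MCMCSettings | None = None,
    model: str = "random",
    check_ess: bool = True,
) -> MTCFit:
    """Inconsistency Bayesian meta-analysis: all three contrast means free."""
    return _fit(data, "ibma", priors, settings, model, check_ess)


def node_split_inconsistency(ibma_fit: MTCFit) -> PosteriorSummary:
    """Node-splitting inconsistency from an IBMA fit's joint draws.

    Per draw, omega = d_BC - (d_AC - d_AB); summarized by its posterior
    mean and equal-tailed 95% interval, significant when the interval
    excludes zero.
    """
    if ibma_fit.kind != "ibma":
        raise ValueError("node splitting requires an IBMA fit")
    needed = {"d_AB", "d_AC", "d_BC"}
    if not needed <= set(ibma_fit.draws):
        raise ValueError("joint posterior draws of d_AB, d_AC, d_BC are required")
    d = ibma_fit.draws
    omega = d["d_BC"] - (d["d_AC"] - d["d_AB"])
    return _summarize({"omega_BC": omega})["omega_BC"]


def summaries_frame(fit: MTCFit):
    """Posterior summaries as a tidy DataFrame (quantity per row)."""
    import pandas as pd

    return pd.DataFrame([s.as_dict() for s in fit.summaries.values()])
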