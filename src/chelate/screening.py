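"""Pool-based Bayesian optimization of ligand selectivity with expected
improvement (EI) on BRR predictions.

Convention: higher ddG (more enantioselective) is better; the incumbent
mu+ is the best *observed* ddG among acquired ligands.  For a Gaussian
prediction N(mu, sigma^2),

    EI = (mu - mu+) Phi(z) + sigma phi(z),   z = (mu - mu+) / sigma

with Phi/phi the standard normal CDF/PDF, and EI = max(mu - mu+, 0) in the
deterministic limit sigma = 0.

The loop refits the full selection pipeline (forward selection + BRR) on
the acquired data at every iteration by default (``refit_selection=False``
keeps the initially selected features and refits only the weights).  It
stops when the highest EI over unacquired ligands falls below
``stop_epsilon`` (default 1e-6), when the literal stop rule is requested —
below the smallest EI at which any past acquisition was made — or when the
pool is exhausted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .modeling import BRRModel, ModelReport, brr_fit, forward_select

__all__ = [
    "expected_improvement",
    "bo_step",
    "bo_loop",
    "retrospective_replay",
    "AcquisitionTrace",
    "BOStep",
]

STOP_EPSILON = 1e-6


def expected_improvement(mu, sigma, best):
    """Closed-form EI of a Gaussian prediction over the incumbent ``best``."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    imp = mu - best
    # z may overflow to +/-inf for extreme mu/sigma ratios; Phi and phi
    # saturate correctly there
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.where(sigma > 0, imp / np.where(sigma > 0, sigma, 1.0), 0.0)
    z = np.clip(z, -40.0, 40.0)  # Phi/phi saturate well inside this range
    ei = np.where(
        sigma > 0,
        imp * norm.cdf(z) + sigma * norm.pdf(z),
        np.maximum(imp, 0.0),
    )
    ei = np.maximum(ei, 0.0)
    return float(ei) if ei.ndim == 0 else ei


@dataclass
class BOStep:
    step: int
    ligand_id: str
    mu: float
    sigma: float
    ei: float
    observed: float
    best_after: float
    features: list[str]


@dataclass
class AcquisitionTrace:
    """Ordered record of one BO run."""

    initial_ids: list[str]
    steps: list[BOStep] = field(default_factory=list)
    stop_reason: str = ""

    @property
    def acquired_ids(self) -> list[str]:
        return [s.ligand_id for s in self.steps]

    @property
    def best_trace(self) -> list[float]:
        return [s.best_after for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.step,
                    "ligand_id": s.ligand_id,
                    "mu": s.mu,
                    "sigma": s.sigma,
                    "ei": s.ei,
                    "observed": s.observed,
                    "best_after": s.best_after,
                }
                for s in self.steps
            ]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _fit_on(frame: pd.DataFrame, obs: dict[str, float], feats: Sequence[str] | None,
            beam: int, max_features: int, candidate_features) -> tuple[BRRModel, list[str]]:
    ids = list(obs)
    y = np.array([obs[i] for i in ids])
    sub = frame.loc[ids]
    if feats is None:
        reports = forward_select(
            sub, y, max_features=max_features, beam=beam,
            candidate_features=candidate_features, allow_small=True, top_k=1,
        )
        feats = reports[0].features
        return reports[0].model, list(feats)
    model = brr_fit(sub[list(feats)].to_numpy(), y, feature_names=list(feats))
    return model, list(feats)


def bo_step(
    model: BRRModel,
    pool,
    acquired: set[str],
    best: float,
) -> tuple[str | None, pd.DataFrame]:
    """Score every unacquired pool ligand and pick the EI argmax.

    Ties are broken by higher predicted mu, then by ligand id.  Returns
    (chosen_id, scores); chosen_id is None only for an empty unacquired set
    (which raises instead).
    """
    frame = pool.frame if hasattr(pool, "frame") else pool
    rest = [i for i in frame.index if i not in acquired]
    if not rest:
        raise ValueError("no unacquired ligands left in the pool")
    X = frame.loc[rest, model.feature_names].to_numpy()
    mu, sigma = model.predict(X, return_std=True)
    ei = expected_improvement(mu, sigma, best)
    scores = pd.DataFrame({"mu": mu, "sigma": sigma, "ei": ei}, index=pd.Index(rest, name="ligand_id"))
    order = sorted(range(len(rest)), key=lambda k: (-ei[k], -mu[k], rest[k]))
    return rest[order[0]], scores


def bo_loop(
    initial: Mapping[str, float],
    pool,
    oracle: Mapping[str, float] | Callable[[str], float],
    stop_epsilon: float = STOP_EPSILON,
    stop_mode: str = "epsilon",
    refit_selection: bool = True,
    max_features: int = 3,
    beam: int = 10,
    candidate_features: Sequence[str] | None = None,
    max_steps: int | None = None,
) -> AcquisitionTrace:
    """Run pool-based BO from an initial batch of observed ligands.

    ``initial`` maps ligand ids to observed ddG (kcal/mol); ``pool`` is a
    FeatureTable/DataFrame over all candidate ligands; ``oracle`` reveals
    the observed ddG of a ligand once acquired.  ``stop_mode`` is
    ``epsilon`` (max EI < stop_epsilon) or ``below_seen`` (max EI below the
    smallest EI at which any acquisition was made).
    """
    frame = pool.frame if hasattr(pool, "frame") else pool
    if len(initial) < 3:
        raise ValueError("the initial batch needs at least 3 observed ligands")
    if stop_mode not in {"epsilon", "below_seen"}:
        raise ValueError(f"unknown stop_mode {stop_mode!r}")
    look = oracle if callable(oracle) else lambda lid: _oracle_lookup(oracle, lid)

    obs = dict(initial)
    trace = AcquisitionTrace(initial_ids=list(initial))
    feats: list[str] | None = None
    min_seen_ei = math.inf
    step = 0
    while True:
        if max_steps is not None and step >= max_steps:
            trace.stop_reason = "max_steps"
            break
        if len(obs) >= len(frame):
            trace.stop_reason = "pool_exhausted"
            break
        model, used = _fit_on(
            frame, obs, None if refit_selection else feats,
            beam=beam, max_features=max_features, candidate_features=candidate_features,
        )
        if feats is None or refit_selection:
            feats = used
        best = max(obs.values())
        chosen, scores = bo_step(model, frame, set(obs), best)
        max_ei = float(scores["ei"].max())
        threshold = stop_epsilon if stop_mode == "epsilon" else max(min_seen_ei, stop_epsilon)
        if max_ei < threshold:
            trace.stop_reason = "converged"
            break
        y_new = float(look(chosen))
        obs[chosen] = y_new
        min_seen_ei = min(min_seen_ei, float(scores.loc[chosen, "ei"]))
        step += 1
        trace.steps.append(
            BOStep(
                step=step,
                ligand_id=chosen,
                mu=float(scores.loc[chosen, "mu"]),
                sigma=float(scores.loc[chosen, "sigma"]),
                ei=float(scores.loc[chosen, "ei"]),
                observed=y_new,
                best_after=max(obs.values()),
                features=list(used),
            )
        )
    return trace


def _oracle_lookup(mapping: Mapping[str, float], lid: str) -> float:
    try:
        return mapping[lid]
    except KeyError:
        raise KeyError(f"oracle has no observation for ligand {lid!r}") from None


@dataclass
class ReplayReport:
    trace: AcquisitionTrace
    best_ligand: str
    historical_position: int    # 1-based reveal index of the best ligand
    bo_position: int | None     # reveals (after the initial batch) BO needed
    bo_total_experiments: int   # initial batch + acquisitions until best found


def retrospective_replay(
    records: pd.DataFrame,
    pool,
    n_initial: int = 3,
    order_column: str | None = None,
    **bo_kwargs,
) -> ReplayReport:
    """Replay a historical screening campaign with BO.

    ``records`` is indexed by ligand_id with a ``ddg`` column, ordered by
    the historical timeline (or by ``order_column``).  The first
    ``n_initial`` historical ligands seed the BO; the oracle is restricted
    to the historical observations.  Reports how many reveals BO needed to
    reach the historically best ligand versus the historical position.
    """
    if order_column is not None:
        records = records.sort_values(order_column)
    ddg = records["ddg"]
    best_ligand = str(ddg.idxmax())
    hist_pos = int(np.argmax(ddg.to_numpy())) + 1
    initial = {str(i): float(ddg[i]) for i in records.index[:n_initial]}
    trace = bo_loop(initial, pool, oracle=ddg.to_dict(), **bo_kwargs)
    if best_ligand in initial:
        bo_pos: int | None = 0
    elif best_ligand in trace.acquired_ids:
        bo_pos = trace.acquired_ids.index(best_ligand) + 1
    else:
        bo_pos = None
    total = n_initial + (bo_pos or len(trace.steps))
    return ReplayReport(
        trace=trace,
        best_ligand=best_ligand,
        historical_position=hist_pos,
        bo_position=bo_pos,
        bo_total_experiments=total,
    )
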