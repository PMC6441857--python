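"""Synthetic hidden population, capture events and RDS survey.

Simulates a closed population of known size N in which each member belongs
to one of K latent classes; class k is captured by source j independently
with probability lambda_kj. The homogeneous single-class case (K = 1) is
the world in which classical capture-recapture is unbiased; K > 1 encodes
heterogeneous capture probabilities, and two explicit violation knobs break
the remaining validity conditions on demand:

* ``dependence_logodds`` — a log-odds tilt on second-source capture given
  first-source capture (behavioral dependence: people captured once are
  easier or harder to capture again);
* ``turnover_fraction`` — after the first capture event that fraction of
  the population emigrates (uncapturable afterwards) and is replaced by
  immigrants capturable only afterwards (open population with constant N).

Members also carry a service-use flag (for the service multiplier) and a
network degree; ``simulate_rds`` grows a configuration-model network over
the population and runs coupon-limited chain referral from seeds, yielding
an RDS sample whose membership can serve as the survey capture source.

All randomness flows through ``numpy`` generators; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .capture_data import CaptureRecord, aggregate_histories, write_capture_histories
from .rds_weights import RDSSample

__all__ = ["SyntheticConfig", "SyntheticTruth", "simulate_population", "simulate_rds", "emit_study_files"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition settings for the simulated world.

    Defaults describe a small border town: N = 2700 women, three capture
    events (two object distributions and the RDS survey) with expected
    margins near 564 / 546 / 408, two latent classes (a larger
    harder-to-reach class and a smaller well-connected one), 30% service
    coverage, mean network degree 8, 7 seeds and 3 coupons.
    """

    true_size: int = 2700
    sources: tuple[str, ...] = ("keychain", "bangle", "rds")
    class_weights: tuple[float, ...] = (0.6, 0.4)
    capture_probs: tuple[tuple[float, ...], ...] = (
        (0.12, 0.11, 0.08),
        (0.34, 0.34, 0.26),
    )
    service_coverage: float = 0.3
    mean_degree: float = 8.0
    degree_dispersion: float = 2.0
    n_seeds: int = 7
    n_coupons: int = 3
    sample_size: int = 408
    replace_depleted_seeds: bool = True
    dependence_logodds: float = 0.0
    turnover_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_size < 1:
            raise ValueError("true_size must be >= 1")
        w = np.asarray(self.class_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError(f"class_weights must be a probability vector, got {self.class_weights}")
        lam = np.asarray(self.capture_probs, dtype=float)
        if lam.shape != (len(self.class_weights), len(self.sources)):
            raise ValueError(
                f"capture_probs must be K x J = {len(self.class_weights)} x "
                f"{len(self.sources)}, got {lam.shape}"
            )
        if ((lam < 0) | (lam > 1)).any():
            raise ValueError("capture probabilities must lie in [0, 1]")
        if not (0.0 <= self.service_coverage <= 1.0):
            raise ValueError("service_coverage must lie in [0, 1]")
        if not (0.0 <= self.turnover_fraction <= 1.0):
            raise ValueError("turnover_fraction must lie in [0, 1]")
        if self.mean_degree < 1.0:
            raise ValueError("mean_degree must be >= 1 (degrees are >= 1)")
        if min(self.n_seeds, self.sample_size) < 1 or self.n_coupons < 0:
            raise ValueError("need n_seeds >= 1, sample_size >= 1, n_coupons >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated population."""

    config: SyntheticConfig
    latent_class: np.ndarray          # (N,) class index
    captures: np.ndarray              # (N, J) binary capture indicators
    service: np.ndarray               # (N,) binary service-use flags
    degrees: np.ndarray               # (N,) reported network degrees >= 1

    def __post_init__(self) -> None:
        N, J = self.captures.shape
        if N != self.config.true_size or J != len(self.config.sources):
            raise ValueError("truth dimensions inconsistent with config")

    @property
    def n_ever_captured(self) -> int:
        return int((self.captures.any(axis=1)).sum())

    @property
    def service_count(self) -> int:
        """The 'program register' count M for the service multiplier."""
        return int(self.service.sum())


def _degrees(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    # degree = 1 + NegBin(r, r/(r+mu-1)): mean mean_degree, dispersion r
    r = cfg.degree_dispersion
    mu = cfg.mean_degree - 1.0
    if mu <= 0:
        return np.ones(cfg.true_size, dtype=np.int64)
    p = r / (r + mu)
    return 1 + rng.negative_binomial(r, p, size=cfg.true_size)


def simulate_population(config: SyntheticConfig, seed: int | None = None) -> SyntheticTruth:
    """Draw latent classes, capture indicators, service flags and degrees.

    The ``seed`` argument overrides ``config.seed`` when given. With the
    violation knobs at zero, captures are independent Bernoulli draws
    within class — the closed, independent world classical
    capture-recapture assumes.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    N, J = config.true_size, len(config.sources)
    w = np.asarray(config.class_weights)
    lam = np.asarray(config.capture_probs)
    z = rng.choice(len(w), size=N, p=w)
    probs = lam[z]  # (N, J)
    captures = (rng.random((N, J)) < probs).astype(np.int8)

    if config.dependence_logodds != 0.0 and J >= 2:
        # re-draw source 2 for first-source captures with tilted odds
        caught1 = captures[:, 0] == 1
        base = np.clip(probs[caught1, 1], 1e-9, 1 - 1e-9)
        logit = np.log(base / (1 - base)) + config.dependence_logodds
        tilted = 1.0 / (1.0 + np.exp(-logit))
        captures[caught1, 1] = (rng.random(caught1.sum()) < tilted).astype(np.int8)

    if config.turnover_fraction > 0.0 and J >= 2:
        n_out = int(round(config.turnover_fraction * N))
        movers = rng.choice(N, size=n_out, replace=False)
        half = n_out // 2
        emigrants, immigrants = movers[:half], movers[half:]
        captures[emigrants, 1:] = 0   # left after the first event
        captures[immigrants, 0] = 0   # arrived after the first event

    service = (rng.random(N) < config.service_coverage).astype(np.int8)
    degrees = _degrees(rng, config)
    return SyntheticTruth(config, z, captures, service, degrees)


def simulate_rds(truth: SyntheticTruth, seed: int | None = None) -> RDSSample:
    """Run coupon-limited chain-referral sampling over a simulated network.

    A configuration-model graph is built from the population's degree
    sequence (self-loops and parallel edges dropped). Recruitment starts
    from uniformly chosen seeds; each participant passes up to
    ``n_coupons`` coupons to unrecruited neighbours chosen uniformly at
    random; sampling is without replacement and proceeds wave by wave
    until the target size is reached or referral chains die out (depleted
    chains are reseeded when configured). Each sampled individual carries
    its reported degree, recruiter, wave, service flag and capture
    indicators.
    """
    cfg = truth.config
    N = cfg.true_size
    if cfg.sample_size > N:
        raise ValueError(f"target sample {cfg.sample_size} exceeds population {N}")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None and cfg.seed is not None else seed)
    deg_seq = truth.degrees.astype(int).tolist()
    if sum(deg_seq) % 2:
        deg_seq[0] += 1
    G = nx.configuration_model(deg_seq, create_using=None, seed=int(rng.integers(2**31)))
    G = nx.Graph(G)  # collapse parallel edges
    G.remove_edges_from(nx.selfloop_edges(G))

    recruited: dict[int, tuple[int | None, int]] = {}  # node -> (recruiter, wave)

    def new_seeds(k: int) -> list[int]:
        pool = np.array([v for v in range(N) if v not in recruited])
        picks = rng.choice(pool, size=min(k, len(pool)), replace=False)
        return [int(v) for v in picks]

    frontier = new_seeds(cfg.n_seeds)
    for s in frontier:
        recruited[s] = (None, 0)
    while len(recruited) < cfg.sample_size:
        next_frontier: list[int] = []
        for node in frontier:
            if len(recruited) >= cfg.sample_size:
                break
            nbrs = [v for v in G.neighbors(node) if v not in recruited]
            rng.shuffle(nbrs)
            for v in nbrs[: cfg.n_coupons]:
                if len(recruited) >= cfg.sample_size:
                    break
                recruited[v] = (node, recruited[node][1] + 1)
                next_frontier.append(v)
        if not next_frontier:
            if not cfg.replace_depleted_seeds:
                break
            seeds = new_seeds(1)
            if not seeds:
                break
            for s in seeds:
                recruited[s] = (None, 0)
            next_frontier = seeds
        frontier = next_frontier

    order = list(recruited)
    rows = {
        "id": [f"p{v}" for v in order],
        "degree": [int(truth.degrees[v]) for v in order],
        "recruiter_id": [
            f"p{recruited[v][0]}" if recruited[v][0] is not None else pd.NA for v in order
        ],
        "wave": [recruited[v][1] for v in order],
        "service_used": [int(truth.service[v]) for v in order],
    }
    for j, src in enumerate(cfg.sources):
        if src == "rds":
            continue
        rows[f"got_{src}"] = [int(truth.captures[v, j]) for v in order]
    df = pd.DataFrame(rows)
    df.attrs["population_index"] = order
    return RDSSample(df)


def combined_capture_records(truth: SyntheticTruth, rds_sample: RDSSample | None = None) -> list[CaptureRecord]:
    """Observed capture histories, with the 'rds' source taken from the
    actual survey sample when one is provided (survey participation *is*
    the capture, mirroring the study design)."""
    cfg = truth.config
    captures = truth.captures.copy()
    if rds_sample is not None and "rds" in cfg.sources:
        j = cfg.sources.index("rds")
        captures[:, j] = 0
        idx = rds_sample.data.attrs.get("population_index")
        if idx is None:
            raise ValueError("RDS sample does not carry population indices")
        captures[np.asarray(idx, dtype=int), j] = 1
    observed = np.flatnonzero(captures.any(axis=1))
    return [
        CaptureRecord(f"p{i}", tuple(int(x) for x in captures[i])) for i in observed
    ]


def emit_study_files(
    truth: SyntheticTruth,
    rds_sample: RDSSample | None,
    output_dir: str | Path,
) -> dict[str, Path]:
    """Write the study file set: capture histories, aggregate table, RDS
    CSV and a ground-truth JSON holding N for recovery tests."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    records = combined_capture_records(truth, rds_sample)
    paths = {
        "capture_histories": out / "capture_histories.csv",
        "aggregate_table": out / "aggregate_table.csv",
        "truth": out / "truth.json",
    }
    try:
        write_capture_histories(records, cfg.sources, paths["capture_histories"])
        aggregate_histories(records, cfg.sources).to_csv(paths["aggregate_table"])
        if rds_sample is not None:
            paths["rds"] = out / "rds.csv"
            rds_sample.to_csv(paths["rds"])
        truth_payload = {
            "true_size": cfg.true_size,
            "service_count": truth.service_count,
            "n_ever_captured": truth.n_ever_captured,
            "config": _jsonable(asdict(cfg)),
        }
        paths["truth"].write_text(json.dumps(truth_payload, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing study files under {out}: {exc}") from exc
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
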