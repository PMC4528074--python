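"""End-to-end experiments: simulate → correct → envelope → infer → evaluate.

An :class:`ExperimentConfig` fixes the simulation conditions, the leakage
correction mode (``none``, ``symmetric`` or ``pairwise``) and the
connectivity metric (``full``, ``partial`` or ``partial_regularised``);
:func:`run_experiment` executes the configured number of repeats and
returns calibrated edge z-scores plus the per-repeat ground truth, from
which :func:`fpr_curve` computes empirical-versus-expected false-positive
curves for single-edge detection.

The pair-wise comparison method (:func:`pairwise_connectivity`) applies
the older two-channel orthogonalisation to every node pair in turn,
averaging over the two seed choices, and — for partial correlations —
regressing the corrected pair from all other nodes before conditioning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from . import envelope as env_mod
from . import netinfer
from . import orthogonalise as orth_mod
from . import simulate as sim_mod
from .errors import DegenerateInputError, ParameterError

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "FPRCurve",
    "run_experiment",
    "pairwise_connectivity",
    "fpr_curve",
    "calibrate_edges",
]

CORRECTIONS = ("none", "symmetric", "pairwise")


@dataclass
class ExperimentConfig:
    """Conditions for one batch of simulated experiments.

    Defaults follow the reference validation conditions: 38 nodes of
    which 5 carry the 6-edge directed network, 600 s recordings, unit
    signal-to-noise power ratio, 4–30 Hz analysis band.
    """

    n_nodes: int = 38
    edges: tuple = sim_mod.FIVE_NODE_EDGES
    duration: float = 600.0
    sampling_rate: float = 100.0
    snr: float = 1.0
    spread: float = 1.0
    band: tuple = (4.0, 30.0)
    correction: str = "symmetric"
    metric: str = "partial_regularised"
    randomise_placement: bool = False
    n_repeats: int = 15
    seed: int = 0
    n_null: int = 50
    cv_folds: int = 10
    cv_refinements: int = 3
    output_dir: str | None = None

    def __post_init__(self):
        if self.correction not in CORRECTIONS:
            raise ParameterError(f"correction must be one of {CORRECTIONS}")
        if self.metric not in netinfer.METRICS:
            raise ParameterError(f"metric must be one of {netinfer.METRICS}")
        if self.correction == "pairwise" and self.metric == "partial_regularised":
            raise ParameterError(
                "regularised partial correlation is not available for the "
                "pair-wise correction"
            )

    def to_json(self) -> str:
        d = asdict(self)
        d["edges"] = [list(e) for e in self.edges]
        d["band"] = list(self.band)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        d["edges"] = tuple(tuple(e) for e in d["edges"])
        d["band"] = tuple(d["band"])
        return cls(**d)


@dataclass
class ExperimentResult:
    """Per-repeat estimates, calibrated z-scores and ground truth."""

    config: ExperimentConfig
    estimates: list
    z_matrices: list
    true_edges: list  # per repeat: frozenset of frozenset node pairs
    null_sd: float
    repeat_seeds: list


@dataclass
class FPRCurve:
    """Empirical false-positive rate against the expected rate."""

    expected_fpr: np.ndarray
    empirical_fpr: np.ndarray  # repeats × grid
    median: np.ndarray = field(init=False)
    lower: np.ndarray = field(init=False)
    upper: np.ndarray = field(init=False)

    def __post_init__(self):
        self.median = np.median(self.empirical_fpr, axis=0)
        self.lower = np.quantile(self.empirical_fpr, 0.025, axis=0)
        self.upper = np.quantile(self.empirical_fpr, 0.975, axis=0)

    def plot(self, ax=None, label=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.expected_fpr, self.lower, self.upper, alpha=0.25)
        ax.plot(self.expected_fpr, self.median, label=label)
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("expected FPR")
        ax.set_ylabel("empirical FPR")
        if label:
            ax.legend()
        return ax


def calibrate_edges(edge_r, null_sd: float) -> netinfer.CalibratedZMatrix:
    """Fisher-transform edge correlations and scale by the null sd."""
    R = np.asarray(edge_r, dtype=float).copy()
    np.fill_diagonal(R, 0.0)
    z = netinfer.fisher_z(np.clip(R, -0.999999, 0.999999)) / null_sd
    np.fill_diagonal(z, 0.0)
    return netinfer.CalibratedZMatrix(z=z, null_sd=null_sd)


def _residualise(target, regressors):
    """Residual of each column of ``target`` on mutually orthogonal regressors."""
    out = target.copy()
    for r in regressors:
        nr = float(np.dot(r, r))
        if nr == 0.0:
            continue
        out = out - np.outer(r, (r @ out) / nr)
    return out


def pairwise_connectivity(
    values,
    metric: str,
    sampling_rate: float,
    lowpass: float = 0.5,
    out_rate: float = 1.0,
    trim: float = 1.0,
) -> netinfer.NetworkEstimate:
    """Connectivity after pair-by-pair orthogonalisation.

    For each node pair the two-channel correction is applied with both
    seed choices and the resulting edge correlations averaged.  For the
    partial metric, each corrected pair is additionally regressed from
    all remaining nodes, every series is enveloped, and the partial
    correlation of the pair's envelopes given the rest is taken.

    ``values`` should already be band-pass filtered.  Collinear pairs are
    recorded as missing (zero) edges with a warning.
    """
    import warnings

    X = np.asarray(values, dtype=float)
    m, n = X.shape
    if metric == "partial_regularised":
        raise ParameterError("regularised partials are not defined for the pair-wise method")
    if metric == "partial" and n < 3:
        raise ParameterError("partial metric needs at least 3 nodes")

    def env_of(cols):
        e = env_mod.hilbert_envelope(cols)
        return env_mod.downsample_envelope(
            e, sampling_rate, lowpass=lowpass, out_rate=out_rate, trim=trim
        ).values

    # raw per-node envelopes reused for the seed columns of the full metric
    raw_env = env_of(X)
    R = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = X[:, i], X[:, j]
            try:
                y_res, x_res = orth_mod.pairwise_orthogonalise(x, y)
            except DegenerateInputError:
                warnings.warn(f"collinear pair ({i}, {j}) recorded as missing edge")
                R[i, j] = R[j, i] = 0.0
                continue
            rs = []
            for seed_ts, other_ts in ((x, y_res), (y, x_res)):
                if metric == "full":
                    e_seed = raw_env[:, i if seed_ts is x else j]
                    e_other = env_of(other_ts[:, None])[:, 0]
                    rs.append(np.corrcoef(e_seed, e_other)[0, 1])
                else:
                    others = np.delete(np.arange(n), [i, j])
                    Z_res = _residualise(X[:, others], (seed_ts, other_ts))
                    block = np.column_stack([seed_ts, other_ts, Z_res])
                    E = env_of(block)
                    S = np.corrcoef(E, rowvar=False)
                    omega = np.linalg.inv(S)
                    rs.append(netinfer.partial_correlation(omega)[0, 1])
            R[i, j] = R[j, i] = float(np.mean(rs))
    omega = np.full((n, n), np.nan)
    return netinfer.NetworkEstimate(
        covariance=R if metric == "full" else np.full((n, n), np.nan),
        precision=omega,
        partial_correlation=R if metric == "partial" else np.full((n, n), np.nan),
        lambda_=0.0,
        metric=metric,
    )


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the configured repeats and calibrate edge scores.

    Each repeat simulates an observation matrix, applies the configured
    leakage correction, computes down-sampled band-limited power
    envelopes and the configured connectivity metric, and scales the
    Fisher-transformed edges by an empirical null standard deviation
    matched to the data's node count, envelope length and temporal
    smoothness (computed once from the first repeat's time-courses).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    repeat_seeds = [int(s) for s in ss.generate_state(cfg.n_repeats) % (2**31)]
    null_seed = int(ss.generate_state(cfg.n_repeats + 1)[-1] % (2**31))

    estimates, z_mats, truths = [], [], []
    null_sd = None
    for r, seed_r in enumerate(repeat_seeds):
        try:
            bundle = sim_mod.simulate_bundle(
                n_nodes=cfg.n_nodes,
                duration=cfg.duration,
                sampling_rate=cfg.sampling_rate,
                edges=cfg.edges,
                snr=cfg.snr,
                spread=cfg.spread,
                randomise_placement=cfg.randomise_placement,
                seed=seed_r,
            )
            Xb = env_mod.bandpass(bundle.observed, cfg.sampling_rate, cfg.band)

            if null_sd is None:
                E_probe = env_mod.envelope_pipeline(Xb, cfg.sampling_rate)
                null_sd = netinfer.null_scaling(
                    cfg.n_nodes,
                    E_probe.n_samples,
                    netinfer.lag1_autocorrelation(E_probe.values),
                    metric=cfg.metric,
                    n_null=cfg.n_null,
                    seed=null_seed,
                )

            if cfg.correction == "pairwise":
                est = pairwise_connectivity(Xb, cfg.metric, cfg.sampling_rate)
            else:
                if cfg.correction == "symmetric":
                    P = orth_mod.symmetric_orthogonalise(Xb).P
                else:
                    P = Xb
                E = env_mod.envelope_pipeline(P, cfg.sampling_rate)
                est = netinfer.network_estimate(
                    E,
                    metric=cfg.metric,
                    folds=cfg.cv_folds,
                    refinements=cfg.cv_refinements,
                )
            z = calibrate_edges(netinfer.edge_values(est), null_sd)
        except Exception as exc:
            raise RuntimeError(
                f"repeat {r} ({cfg.correction}/{cfg.metric}) failed: {exc}"
            ) from exc
        estimates.append(est)
        z_mats.append(z)
        truths.append(bundle.truth.undirected_edges)

    result = ExperimentResult(
        config=cfg,
        estimates=estimates,
        z_matrices=z_mats,
        true_edges=truths,
        null_sd=float(null_sd),
        repeat_seeds=repeat_seeds,
    )
    if cfg.output_dir is not None:
        _write_artifacts(result)
    return result


def _write_artifacts(result: ExperimentResult) -> None:
    import pandas as pd

    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": json.loads(result.config.to_json()),
        "repeat_seeds": result.repeat_seeds,
        "null_sd": result.null_sd,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for r, (est, z, truth) in enumerate(
        zip(result.estimates, result.z_matrices, result.true_edges)
    ):
        pd.DataFrame(netinfer.edge_values(est)).to_csv(out / f"edges_r_{r:03d}.csv", index=False)
        pd.DataFrame(z.z).to_csv(out / f"edges_z_{r:03d}.csv", index=False)
        with open(out / f"true_edges_{r:03d}.txt", "w") as fh:
            for e in sorted(tuple(sorted(pair)) for pair in truth):
                fh.write(f"{e[0]}\t{e[1]}\n")


def fpr_curve(z_matrices, true_edges, grid=None) -> FPRCurve:
    """False detections among null edges as the z threshold moves.

    For each expected rate α the detection threshold is the standard
    normal upper-α critical value; the empirical FPR of a repeat is the
    fraction of its true-null edges exceeding it.

    ``true_edges`` may be a single edge set shared by all repeats or one
    per repeat; edges are undirected node pairs.
    """
    if grid is None:
        grid = np.linspace(0.005, 0.5, 50)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ParameterError("expected-FPR grid must lie strictly inside (0, 1)")
    mats = [np.asarray(getattr(z, "z", z), dtype=float) for z in z_matrices]
    n = mats[0].shape[0]
    if isinstance(true_edges, (set, frozenset)):
        true_edges = [true_edges] * len(mats)
    iu = np.triu_indices(n, k=1)
    crit = stats.norm.isf(grid)
    rows = []
    for zmat, truth in zip(mats, true_edges):
        truth_norm = {frozenset(e) for e in truth}
        null_mask = np.array(
            [frozenset((int(a), int(b))) not in truth_norm for a, b in zip(*iu)]
        )
        if not null_mask.any():
            raise ParameterError("no true-null edges to evaluate")
        null_z = zmat[iu][null_mask]
        rows.append((null_z[:, None] > crit[None, :]).mean(axis=0))
    return FPRCurve(expected_fpr=grid, empirical_fpr=np.asarray(rows))
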