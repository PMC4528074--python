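"""Model/Results interface over the leakage-corrected connectome pipeline.

:class:`EnvelopeConnectome` bundles the full analysis of one recording —
band-pass filtering, zero-lag leakage correction, power-envelope
extraction, Gaussian-graphical network estimation and empirical-null
calibration — behind a fit interface:

>>> from leakmend import EnvelopeConnectome, simulate
>>> bundle = simulate.simulate_bundle(n_nodes=10, duration=120, seed=7)
>>> model = EnvelopeConnectome(bundle.observed, sampling_rate=100.0)
>>> res = model.fit(seed=7)
>>> print(res.summary())          # doctest: +SKIP

The returned :class:`EnvelopeConnectomeResults` carries the covariance /
precision / partial-correlation estimates, the selected regularisation
strength, calibrated edge z-scores, the FDR-thresholded edge mask and a
tabular summary; plotting hangs off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import envelope as env_mod
from . import netinfer
from . import orthogonalise as orth_mod
from .errors import ParameterError
from .pipeline import CORRECTIONS, calibrate_edges, pairwise_connectivity

__all__ = ["EnvelopeConnectome", "EnvelopeConnectomeResults"]


class EnvelopeConnectome:
    """Envelope-correlation network model for multichannel oscillatory data.

    Parameters
    ----------
    data : array-like, samples × nodes
        Raw node/region time-courses.
    sampling_rate : float
        Sampling rate of ``data`` in Hz.
    node_labels : sequence of str, optional
    correction : {"symmetric", "pairwise", "none"}
        Zero-lag leakage correction applied before envelope extraction.
    band : (low, high) Hz
        Analysis band for the band-pass filter.
    metric : {"full", "partial", "partial_regularised"}
        Connectivity metric computed between the power envelopes.
    lowpass, envelope_rate, trim
        Envelope low-pass cut-off (Hz), output rate (Hz) and edge trim (s).
    """

    def __init__(
        self,
        data,
        sampling_rate: float,
        node_labels=None,
        correction: str = "symmetric",
        band=(4.0, 30.0),
        metric: str = "partial_regularised",
        lowpass: float = 0.5,
        envelope_rate: float = 1.0,
        trim: float = 1.0,
    ):
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be a 2-D samples × nodes matrix")
        if correction not in CORRECTIONS:
            raise ParameterError(f"correction must be one of {CORRECTIONS}")
        if metric not in netinfer.METRICS:
            raise ParameterError(f"metric must be one of {netinfer.METRICS}")
        self.sampling_rate = float(sampling_rate)
        self.node_labels = (
            [str(s) for s in node_labels]
            if node_labels is not None
            else [f"node_{i}" for i in range(self.data.shape[1])]
        )
        self.correction = correction
        self.band = tuple(band)
        self.metric = metric
        self.lowpass = lowpass
        self.envelope_rate = envelope_rate
        self.trim = trim

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sampling_rate: float, **kwargs):
        """Build the model from a DataFrame whose columns are the nodes."""
        return cls(
            df.to_numpy(dtype=float), sampling_rate, node_labels=list(df.columns), **kwargs
        )

    @classmethod
    def from_simulation(cls, bundle, **kwargs):
        """Build the model from a :class:`~leakmend.simulate.SimulationBundle`."""
        return cls(bundle.observed, bundle.sampling_rate, **kwargs)

    def fit(
        self,
        lambda_=None,
        folds: int = 10,
        refinements: int = 3,
        calibrate: bool = True,
        n_null: int = 50,
        seed=None,
    ) -> "EnvelopeConnectomeResults":
        """Run the pipeline and return the fitted results.

        ``lambda_=None`` triggers cross-validated selection for the
        regularised metric; ``calibrate=False`` skips the empirical-null
        scaling (z-scores are then raw Fisher transforms).
        """
        Xb = env_mod.bandpass(self.data, self.sampling_rate, self.band)
        ortho = None
        if self.correction == "pairwise":
            estimate = pairwise_connectivity(
                Xb, self.metric, self.sampling_rate,
                lowpass=self.lowpass, out_rate=self.envelope_rate, trim=self.trim,
            )
            envelopes = env_mod.envelope_pipeline(
                Xb, self.sampling_rate,
                lowpass=self.lowpass, out_rate=self.envelope_rate, trim=self.trim,
            )
        else:
            P = Xb
            if self.correction == "symmetric":
                ortho = orth_mod.symmetric_orthogonalise(Xb)
                P = ortho.P
            envelopes = env_mod.envelope_pipeline(
                P, self.sampling_rate,
                lowpass=self.lowpass, out_rate=self.envelope_rate, trim=self.trim,
            )
            estimate = netinfer.network_estimate(
                envelopes, metric=self.metric, lambda_=lambda_,
                folds=folds, refinements=refinements,
            )
        null_sd = 1.0
        if calibrate:
            null_sd = netinfer.null_scaling(
                self.data.shape[1],
                envelopes.n_samples,
                netinfer.lag1_autocorrelation(envelopes.values),
                metric=self.metric,
                n_null=n_null,
                seed=seed,
            )
        z = calibrate_edges(netinfer.edge_values(estimate), null_sd)
        return EnvelopeConnectomeResults(self, estimate, z, envelopes, ortho)


class EnvelopeConnectomeResults:
    """Estimates, uncertainties and diagnostics of a fitted connectome."""

    def __init__(self, model, estimate, z, envelopes, orthogonalisation=None):
        self.model = model
        self.estimate = estimate
        self.z_matrix = z
        self.envelopes = envelopes
        self.orthogonalisation = orthogonalisation

    @property
    def covariance(self):
        return self.estimate.covariance

    @property
    def precision(self):
        return self.estimate.precision

    @property
    def partial_correlation(self):
        return self.estimate.partial_correlation

    @property
    def lambda_(self):
        return self.estimate.lambda_

    @property
    def z(self):
        return self.z_matrix.z

    @property
    def null_sd(self):
        return self.z_matrix.null_sd

    def fdr_edges(self, q: float = 0.05):
        """``(z_threshold, mask)`` after Benjamini–Hochberg control at ``q``."""
        return netinfer.fdr_threshold(self.z_matrix, q=q)

    def edge_table(self, q: float = 0.05) -> pd.DataFrame:
        """Long-format edge table: node_i, node_j, r, z, survives_fdr."""
        labels = self.model.node_labels
        R = netinfer.edge_values(self.estimate)
        _, mask = self.fdr_edges(q)
        n = len(labels)
        iu = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "node_i": [labels[i] for i in iu[0]],
                "node_j": [labels[j] for j in iu[1]],
                "r": R[iu],
                "z": self.z[iu],
                "survives_fdr": mask[iu],
            }
        )

    def summary(self, q: float = 0.05, top: int = 10) -> str:
        """Readable overview of the fit."""
        tbl = self.edge_table(q)
        z_thr, mask = self.fdr_edges(q)
        n_sig = int(mask.sum() // 2)
        lines = [
            "Envelope connectome fit",
            "=" * 55,
            f"nodes:                {len(self.model.node_labels)}",
            f"correction:           {self.model.correction}",
            f"metric:               {self.estimate.metric}",
            f"band:                 {self.model.band[0]:g}-{self.model.band[1]:g} Hz",
            f"envelope samples:     {self.envelopes.n_samples} @ {self.envelopes.envelope_rate:g} Hz",
            f"lambda:               {self.estimate.lambda_:.4g}",
            f"null edge sd:         {self.z_matrix.null_sd:.4g}",
            f"FDR {q:.0%} z-threshold:  "
            + (f"{z_thr:.3f}" if np.isfinite(z_thr) else "none survive"),
            f"significant edges:    {n_sig} of {len(tbl)}",
        ]
        if self.orthogonalisation is not None:
            o = self.orthogonalisation
            lines.append(
                f"orthogonalisation:    {o.iterations} iterations, "
                f"converged={o.converged}, error={o.error:.4g}"
            )
        lines.append("-" * 55)
        lines.append(f"top edges by z (first {top}):")
        show = tbl.sort_values("z", ascending=False).head(top)
        lines.append(
            show.to_string(
                index=False,
                formatters={"r": "{:.3f}".format, "z": "{:.2f}".format},
            )
        )
        return "\n".join(lines)

    def plot_matrix(self, which: str = "z", ax=None):
        """Heat map of the edge matrix (``z``, ``r`` or ``precision``)."""
        import matplotlib.pyplot as plt

        mats = {
            "z": self.z,
            "r": netinfer.edge_values(self.estimate),
            "precision": self.precision,
        }
        if which not in mats:
            raise ParameterError(f"which must be one of {sorted(mats)}")
        M = mats[which].copy()
        np.fill_diagonal(M, 0.0)
        if ax is None:
            _, ax = plt.subplots()
        vmax = np.abs(M).max() or 1.0
        im = ax.imshow(M, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.figure.colorbar(im, ax=ax, label=which)
        ax.set_xlabel("node")
        ax.set_ylabel("node")
        return ax
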