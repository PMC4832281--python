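"""Model/Results front end for calcium-signature decoding.

:class:`CalciumDecodingModel` bundles a calcium signature (the data) with the
binding-network and gene parameters; :meth:`~CalciumDecodingModel.fit` runs
the full pipeline — equilibrate at the control Ca2+, simulate the clamped
19-species binding network, drive the delayed gene stage — and returns a
:class:`DecodingResults` carrying the fold-change series, diagnostics and a
``summary()`` table, in the spirit of a statsmodels results object.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import decoding
from .binding import BaseParameters, BindingModel
from .genes import GeneParams, potential_fold_curve
from .signatures import CalciumTrace, PiecewiseSpec, make_piecewise, read_trace

__all__ = ["CalciumDecodingModel", "DecodingResults"]


class CalciumDecodingModel:
    """Decoding of one calcium signature into a gene-expression response.

    Parameters
    ----------
    trace
        Clamped cytosolic Ca2+ time course (seconds, uM).
    binding_params
        Anchored binding constants and totals; remaining constants are
        completed by detailed balance.
    gene_params
        Transcription parameters of the reporter gene class.
    control_ca
        Resting Ca2+ level (uM) defining the control steady state all fold
        changes are measured against.
    readout_s
        Comparison time for the decoded expression fold (s after signature
        onset).
    """

    def __init__(
        self,
        trace: CalciumTrace,
        binding_params: BaseParameters | None = None,
        gene_params: GeneParams | None = None,
        control_ca: float = 0.10,
        readout_s: float = 3600.0,
    ):
        self.trace = trace
        self.binding_params = binding_params or BaseParameters()
        self.gene_params = gene_params or GeneParams()
        self.control_ca = control_ca
        self.readout_s = readout_s
        self.network = BindingModel(self.binding_params, control_ca=control_ca)

    # ---- constructors -------------------------------------------------

    @classmethod
    def from_piecewise(cls, spec: PiecewiseSpec, **kwargs) -> "CalciumDecodingModel":
        """Build from a square-wave signature specification."""
        return cls(make_piecewise(spec), **kwargs)

    @classmethod
    def from_file(cls, path, **kwargs) -> "CalciumDecodingModel":
        """Build from a two-column (time_s, ca_um) trace file."""
        return cls(read_trace(path), **kwargs)

    # ---- estimation ---------------------------------------------------

    def fit(self) -> "DecodingResults":
        """Run the full decoding pipeline and return the results object."""
        res = decoding.decode(
            self.network, self.trace, self.gene_params, readout_s=self.readout_s
        )
        return DecodingResults(self, res)

    def fit_cam_total(
        self,
        anchor: PiecewiseSpec,
        target_fold: float,
        bounds: tuple[float, float] = (0.1, 1000.0),
    ) -> "CalciumDecodingModel":
        """Return a copy of the model with total CaM calibrated to an anchor.

        Total CaM is the one concentration without an experimental value; it
        is estimated by requiring the anchor signature to produce
        ``target_fold`` expression change at the readout time.
        """
        cam = decoding.calibrate_cam_total(
            self.network, anchor, target_fold, self.gene_params,
            bounds=bounds, readout_s=self.readout_s,
        )
        return CalciumDecodingModel(
            self.trace,
            replace(self.binding_params, cam_total=cam),
            self.gene_params,
            control_ca=self.control_ca,
            readout_s=self.readout_s,
        )


class DecodingResults:
    """Fitted decoding of one signature: fold-change series plus diagnostics.

    Attributes mirror the underlying :class:`~camdecode.decoding.FoldChangeResult`:
    ``times``, ``ca_fold``, ``m22x_fold``, ``mrna_fold`` (all relative to the
    control steady state), and scalar diagnostics (conservation residual of
    the simulated trajectory, control levels, totals).
    """

    def __init__(self, model: CalciumDecodingModel, res: decoding.FoldChangeResult):
        self.model = model
        self._res = res
        self.times = res.times
        self.ca_fold = res.ca_fold
        self.m22x_fold = res.m22x_fold
        self.mrna_fold = res.mrna_fold
        self.readout_s = res.readout_s
        self.control_m22x = res.control_m22x
        self.conservation_residual = res.conservation_residual

    @property
    def fold_at_readout(self) -> float:
        return self._res.fold_at(self.readout_s)

    @property
    def induced(self) -> bool:
        """Whether the decoded fold clears the 1.5-fold induction threshold."""
        return self.fold_at_readout >= decoding.INDUCTION_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        """Fold-change series as a tidy DataFrame indexed by time."""
        data = {
            "ca_fold": self.ca_fold,
            "m22x_fold": self.m22x_fold,
        }
        if self.mrna_fold is not None:
            data["mrna_fold"] = self.mrna_fold
        return pd.DataFrame(data, index=pd.Index(self.times, name="time_s"))

    def potential_curve(self, n: int = 200):
        """Potential (steady-state) fold curve over the visited complex range."""
        m22x = self.m22x_fold * self.control_m22x
        grid = np.geomspace(
            max(self.control_m22x * 1e-2, np.min(m22x[m22x > 0])),
            max(np.max(m22x), self.control_m22x) * 1.5,
            n,
        )
        return grid, potential_fold_curve(grid, self.model.gene_params, self.control_m22x)

    def summary(self) -> str:
        s = self._res.summary
        bp, gp = self.model.binding_params, self.model.gene_params
        rows = [
            ("Signature span (s)", f"{self.times[0]:.0f} .. {self.model.trace.times[-1]:.0f}"),
            ("Control Ca (uM)", f"{self.model.control_ca:.4g}"),
            ("Total CaM / CAMTA (uM)", f"{bp.cam_total:.4g} / {bp.camta_total:.4g}"),
            ("DNA-binding affinity k4 (uM)", f"{gp.k4:.4g}"),
            ("Delay tau (s)", f"{gp.tau:.4g}"),
            ("Regulation mode", gp.mode),
            ("Peak Ca fold", f"{s['peak_ca_fold']:.4g}"),
            ("Peak active-complex fold", f"{s['peak_m22x_fold']:.4g}"),
            ("mRNA fold at readout", f"{self.fold_at_readout:.4g}"),
            (f"Induced (>= {decoding.INDUCTION_THRESHOLD}-fold)", str(self.induced)),
            ("Readout time (s)", f"{self.readout_s:.0f}"),
            ("Conservation residual (rel.)", f"{self.conservation_residual:.2e}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Calcium signature decoding results", "=" * 50]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the fold-change series (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.ca_fold, label="Ca$^{2+}$ fold", lw=0.8)
        ax.plot(self.times, self.m22x_fold, label="active complex fold", lw=0.8)
        if self.mrna_fold is not None:
            ax.plot(self.times, self.mrna_fold, label="mRNA fold", lw=1.5)
        ax.axvline(self.readout_s, color="grey", ls=":", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("fold change vs control")
        ax.set_yscale("log")
        ax.legend()
        return ax
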