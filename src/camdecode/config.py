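"""Run configuration: flat YAML files mapped onto the parameter dataclasses.

A run config has four optional sections — ``model`` (binding network),
``gene``, ``signature`` and ``analysis`` — plus ``seed``.  Unknown keys are
rejected with their full path so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .binding import BaseParameters
from .genes import GeneParams
from .signatures import PiecewiseSpec

__all__ = ["RunConfig", "load_config", "resolve_signature", "dump_config"]

_MODEL_EXTRA = {"control_ca"}
_SIGNATURE_KEYS = {
    "kind", "file", "average", "ca_max", "ca_min", "period", "duration",
    "onset", "baseline", "peak", "rest", "n_spikes", "rise", "decay",
    "total", "plateau", "noise_sd", "dt",
}
_ANALYSIS_KEYS = {
    "readout_s", "periods", "spike_counts", "target_fold", "bounds",
    "ca_folds",
}


def _fields(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown config key(s) in [{section}]: "
            + ", ".join(f"{section}.{k}" for k in sorted(unknown))
        )


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration for one reproducible run."""

    base: BaseParameters
    gene: GeneParams
    control_ca: float = 0.10
    signature: dict = dataclasses.field(default_factory=dict)
    analysis: dict = dataclasses.field(default_factory=dict)
    seed: int = 0


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a run config from a YAML file path or a dict."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    _check_keys("<root>", raw, {"model", "gene", "signature", "analysis", "seed"})

    model_raw = dict(raw.get("model") or {})
    _check_keys("model", model_raw, _fields(BaseParameters) | _MODEL_EXTRA)
    control_ca = float(model_raw.pop("control_ca", 0.10))
    base = BaseParameters(**model_raw)

    gene_raw = dict(raw.get("gene") or {})
    _check_keys("gene", gene_raw, _fields(GeneParams))
    gene = GeneParams(**gene_raw)

    sig_raw = dict(raw.get("signature") or {})
    _check_keys("signature", sig_raw, _SIGNATURE_KEYS)

    ana_raw = dict(raw.get("analysis") or {})
    _check_keys("analysis", ana_raw, _ANALYSIS_KEYS)

    return RunConfig(
        base=base,
        gene=gene,
        control_ca=control_ca,
        signature=sig_raw,
        analysis=ana_raw,
        seed=int(raw.get("seed", 0)),
    )


def resolve_signature(cfg: RunConfig):
    """Build the configured calcium trace (piecewise, synthetic, or file)."""
    from .signatures import make_piecewise, make_synthetic, read_trace

    sig = dict(cfg.signature)
    kind = sig.pop("kind", "piecewise")
    if "file" in sig:
        return read_trace(sig["file"])
    if kind == "piecewise":
        dt = sig.pop("dt", 0.1)
        spec_kwargs = {k: v for k, v in sig.items() if k in _fields(PiecewiseSpec)}
        return make_piecewise(PiecewiseSpec(**spec_kwargs), dt=dt)
    sig.setdefault("seed", cfg.seed)
    return make_synthetic(kind, **sig)


def dump_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved config next to the run outputs."""
    out = {
        "model": {**dataclasses.asdict(cfg.base), "control_ca": cfg.control_ca},
        "gene": dataclasses.asdict(cfg.gene),
        "signature": cfg.signature,
        "analysis": cfg.analysis,
        "seed": cfg.seed,
    }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
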