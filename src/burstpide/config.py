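"""Experiment configuration, serialisation, and the preset runner.

Configs are TOML with a versioned schema; unknown keys are rejected and the
fully resolved configuration is echoed into the output directory, so a run
directory is reproducible from its own artefacts.  Densities are written as
CSV (1D: ``x,density``; 2D: long format ``x1,x2,density``) and optionally
HDF5; entropy traces as CSV plus a JSON fit record.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import entropy_experiment, reference_stationary
from .grids import Axis, DensityGrid, gaussian_initial_condition
from .kernels import CrossFeedback2D, HillFeedback1D
from .presets import get_preset
from .solver import ModelND, default_axes, simulate
from .stationary import Model1D, classify_shape

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "load_config",
    "dump_toml",
    "run_preset",
    "run_experiment",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


@dataclass
class ExperimentConfig:
    """Resolved experiment description (schema version 1)."""

    schema: int = SCHEMA_VERSION
    preset: str | None = None
    model: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    integrator: dict = field(default_factory=dict)
    initial: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    seed: int = 0  # reserved; the pipeline is deterministic


_ALLOWED = {
    "": {"schema", "preset", "model", "grid", "integrator", "initial", "output", "seed"},
    "model": {"kind", "a", "b", "km", "gamma", "feedback"},
    "model.feedback": {"variant", "H", "K", "epsilon", "H_cross", "factors", "params"},
    "grid": {"n", "x_max", "kappa"},
    "integrator": {"method", "t_end", "n_save", "dt", "cfl", "eta"},
    "initial": {"kind", "means", "sds", "path"},
    "output": {"dir", "formats"},
}


def _check_keys(d: dict, scope: str) -> None:
    allowed = _ALLOWED.get(scope)
    if allowed is None:
        return
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in [{scope or 'top level'}]")
    for key, val in d.items():
        if isinstance(val, dict):
            _check_keys(val, f"{scope}.{key}".lstrip("."))


def load_config(path) -> ExperimentConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    _check_keys(raw, "")
    if raw.get("schema", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {raw.get('schema')}")
    return ExperimentConfig(**raw)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ConfigError(f"cannot serialise {type(v)!r} to TOML")


def dump_toml(data: dict, prefix: str = "") -> str:
    """Minimal TOML emitter for nested dicts of scalars and lists."""
    lines, tables = [], []
    for key, val in data.items():
        if isinstance(val, dict):
            tables.append((key, val))
        elif val is not None:
            lines.append(f"{key} = {_toml_value(val)}")
    out = "\n".join(lines)
    for key, val in tables:
        name = f"{prefix}{key}"
        out += f"\n\n[{name}]\n" + dump_toml(val, prefix=f"{name}.")
    return out.strip() + "\n"


def build_model(cfg: ExperimentConfig):
    m = cfg.model
    kind = m.get("kind", "1d")
    if kind == "1d":
        fb = m.get("feedback")
        feedback = None
        if fb is not None and fb.get("variant", "hill") != "open_loop":
            feedback = HillFeedback1D(H=int(fb["H"]), K=float(fb["K"]), epsilon=float(fb["epsilon"]))
        return Model1D(a=float(m["a"]), b=float(m["b"]), feedback=feedback)
    if kind == "nd":
        fb = m.get("feedback")
        feedback = None
        if fb is not None:
            variant = fb["variant"]
            if variant == "mutual_repression":
                feedback = CrossFeedback2D(
                    variant=variant,
                    K=tuple(map(float, fb["K"])),
                    epsilon=tuple(map(float, fb["epsilon"])),
                    H_cross=tuple(map(int, fb["H_cross"])),
                )
            elif variant == "product_of_1d":
                feedback = CrossFeedback2D(
                    variant=variant,
                    factors=tuple(
                        HillFeedback1D(H=int(f["H"]), K=float(f["K"]), epsilon=float(f["epsilon"]))
                        for f in fb["factors"]
                    ),
                )
            elif variant == "general_cross":
                feedback = CrossFeedback2D(variant=variant, params=tuple(fb["params"]))
            else:
                raise ConfigError(f"unknown feedback variant {variant!r}")
        return ModelND(
            km=tuple(map(float, m["km"])),
            b=tuple(map(float, m["b"])),
            feedback=feedback,
            gamma=tuple(map(float, m["gamma"])) if "gamma" in m else None,
        )
    raise ConfigError(f"unknown model kind {kind!r}")


def _write_density(state: DensityGrid, path: Path) -> None:
    if state.ndim == 1:
        df = pd.DataFrame({"x": state.axes[0].centers, "density": state.values})
    elif state.ndim == 2:
        x1, x2 = state.meshgrid()
        df = pd.DataFrame(
            {"x1": x1.ravel(), "x2": x2.ravel(), "density": state.values.ravel()}
        )
    else:
        raise ValueError("CSV output supports 1D and 2D grids")
    df.to_csv(path, index=False)


def _write_hdf5(report, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for ax_i, ax in enumerate(report.states[0].axes):
            fh.create_dataset(f"axis{ax_i}/centers", data=ax.centers)
        fh.create_dataset("times", data=np.asarray(report.times))
        for k, state in enumerate(report.states):
            fh.create_dataset(f"density/{k:05d}", data=state.values)
        fh.attrs["method"] = report.method
        fh.attrs["dt"] = report.dt


def _fit_with_fallback(trace, horizon: float) -> None:
    """Fit the decay on a fixed relative window so fitted rates are
    comparable across resolutions; fall back to the adaptive window, and
    leave the fit fields empty for horizons too short to fit."""
    from .entropy import fit_decay_rate

    try:
        fit_decay_rate(trace, window=(0.25 * horizon, 0.625 * horizon))
    except ValueError:
        try:
            fit_decay_rate(trace)
        except ValueError:
            pass


def run_preset(
    name: str,
    outdir,
    n_cells: int | None = None,
    t_end: float | None = None,
    method: str = "split",
    write_hdf5: bool = False,
) -> Path:
    """Run a printed experiment end to end and write its artefact directory.

    1D presets: stationary analysis (normalisation + shape classification),
    simulation from the preset Gaussian, entropy trace and decay fit.
    2D presets: simulation and the entropy trace against the product
    reference (independent genes) or a long-time operational reference.
    """
    preset = get_preset(name)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = n_cells or preset.n_cells
    horizon = t_end or preset.t_end

    if isinstance(preset.model, Model1D):
        dens = classify_shape(preset.model)
        axis = Axis(x_max=dens.x_max, n=n)
        pinf = dens.cell_averages(axis.faces)
        with open(outdir / "classification.json", "w") as fh:
            json.dump(
                {
                    "parameters": preset.record,
                    "case": dens.shape_case,
                    "modes": list(dens.mode_locations),
                    "Z": dens.Z,
                    "singular_at_zero": dens.singular_at_zero,
                },
                fh, indent=2,
            )
        pd.DataFrame({"x": axis.centers, "density": pinf}).to_csv(
            outdir / "stationary.csv", index=False
        )
        p0 = gaussian_initial_condition(preset.ic_means, preset.ic_sds, (axis,))
        trace = entropy_experiment(
            preset.model, p0, horizon, pinf, n_save=100, d2_every=10, method=method,
            fit=False,
        )
        _fit_with_fallback(trace, horizon)
        model_used = preset.model
        axes = (axis,)
    else:
        axes = default_axes(preset.model, n)
        p0 = gaussian_initial_condition(preset.ic_means, preset.ic_sds, axes)
        if getattr(preset.model.feedback, "variant", None) == "product_of_1d":
            parts = []
            for i, fb in enumerate(preset.model.feedback.factors):
                m1 = Model1D(a=preset.model.km[i] / preset.model.gamma[i],
                             b=preset.model.b[i], feedback=fb)
                parts.append(classify_shape(m1).cell_averages(axes[i].faces))
            pinf = np.multiply.outer(parts[0], parts[1])
            pinf /= pinf.sum() * np.prod([ax.dx for ax in axes])
        else:
            ref = reference_stationary(preset.model, p0, t_max=120.0, tol=1e-10)
            pinf = ref.values
        trace = entropy_experiment(
            preset.model, p0, horizon, pinf, n_save=100, d2_every=0, method=method,
            fit=False,
        )
        _fit_with_fallback(trace, horizon)
        model_used = preset.model

    report = simulate(model_used, p0, horizon, method=method)
    _write_density(report.final(), outdir / "density_final.csv")
    if write_hdf5 and len(axes) == 2:
        _write_hdf5(report, outdir / "trajectory.h5")

    trace_df = pd.DataFrame({"t": trace.times, "G2": trace.G2})
    if trace.D2 is not None:
        d2 = pd.Series(trace.D2, index=trace.d2_times)
        trace_df["D2"] = trace_df["t"].map(d2)
    trace_df.to_csv(outdir / "entropy_trace.csv", index=False)
    with open(outdir / "fit.json", "w") as fh:
        json.dump(
            {
                "entropy_rate": trace.entropy_rate,
                "norm_rate": trace.fitted_rate,
                "fit_window": trace.fit_window,
                "r_squared": trace.fit_r_squared,
                "final_mass": report.final().mass(),
            },
            fh, indent=2,
        )

    resolved = ExperimentConfig(
        preset=name,
        grid={"n": n},
        integrator={"method": method, "t_end": horizon},
        output={"dir": str(outdir)},
    )
    (outdir / "config.toml").write_text(dump_toml(asdict(resolved)))
    return outdir


def run_experiment(cfg: ExperimentConfig, outdir=None) -> Path:
    """Run an explicit (non-preset) configuration."""
    outdir = Path(outdir or cfg.output.get("dir", "out"))
    if cfg.preset is not None:
        return run_preset(
            cfg.preset,
            outdir,
            n_cells=cfg.grid.get("n"),
            t_end=cfg.integrator.get("t_end"),
            method=cfg.integrator.get("method", "split"),
        )
    outdir.mkdir(parents=True, exist_ok=True)
    model = build_model(cfg)
    n = int(cfg.grid.get("n", 512))
    if isinstance(model, Model1D):
        from .stationary import normalise

        x_max = float(cfg.grid.get("x_max", 0.0)) or normalise(model).x_max
        axes = (Axis(x_max=x_max, n=n),)
    else:
        axes = default_axes(model, n, kappa=float(cfg.grid.get("kappa", 4.0)))
    init = cfg.initial
    if init.get("kind", "gaussian") == "gaussian":
        p0 = gaussian_initial_condition(init["means"], init["sds"], axes)
    elif init["kind"] == "stationary":
        if not isinstance(model, Model1D):
            raise ConfigError("stationary initial data needs the 1D closed form")
        from .stationary import normalise

        p0 = DensityGrid(axes, normalise(model).cell_averages(axes[0].faces))
    elif init["kind"] == "table":
        df = pd.read_csv(init["path"])
        p0 = DensityGrid(axes, df["density"].to_numpy().reshape([ax.n for ax in axes]))
        p0 = p0.normalised()
    else:
        raise ConfigError(f"unknown initial condition kind {init.get('kind')!r}")
    integ = cfg.integrator
    report = simulate(
        model, p0, float(integ.get("t_end", 10.0)),
        method=integ.get("method", "split"),
        dt=float(integ["dt"]) if integ.get("dt") else None,
    )
    _write_density(report.final(), outdir / "density_final.csv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {"times": report.times, "mass": report.mass_history,
             "min": report.min_history, "dt": report.dt, "status": report.status},
            fh, indent=2,
        )
    (outdir / "config.toml").write_text(dump_toml(asdict(cfg)))
    return outdir
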