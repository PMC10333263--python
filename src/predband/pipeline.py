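"""End-to-end experiment presets: scenario -> data -> training -> predictions
-> PCA report.

Each preset is a YAML config shipped with the package (``presets/``) that
names a training scenario, the model variant to train, the variables included
in training, test protocols, and optional parameter perturbations.  Running a
preset writes the measurement table, posterior samples, convergence
diagnostics, prediction bands, the deviation spectrum and a plain-text
summary into an output directory; given the same seed and scale the outputs
are bit-identical.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analysis, inference, models, synthetic

__all__ = ["ExperimentConfig", "list_presets", "load_preset", "run_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """A named experiment: what to train, on which data, and what to report."""

    name: str
    description: str = ""
    scenario: str = "cascade_train"
    model: str = "nominal"
    train_on: list[str] = field(default_factory=list)  # empty -> data only
    protocols: list[str] = field(default_factory=list)  # test protocols
    perturbations: list[dict] = field(default_factory=list)  # {parameter, factor}
    level: float = 0.8
    seed: int = 0
    scale_factor: float = 1.0
    n_chains: int = 8

    def __post_init__(self):
        models.get_model(self.model)  # must resolve
        if self.scenario not in synthetic.SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for p in self.protocols:
            models.get_protocol(p)

    @classmethod
    def from_yaml(cls, path_or_text) -> "ExperimentConfig":
        if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
            with open(path_or_text) as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(path_or_text)
        return cls(**raw)


def _preset_dir():
    return importlib.resources.files("predband") / "presets"


def list_presets() -> dict[str, str]:
    """Available preset names with one-line descriptions."""
    out = {}
    for entry in sorted(_preset_dir().iterdir()):
        if entry.name.endswith(".yaml"):
            raw = yaml.safe_load(entry.read_text())
            out[raw["name"]] = raw.get("description", "")
    return out


def load_preset(name: str) -> ExperimentConfig:
    path = _preset_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(list_presets())}") from None
    return ExperimentConfig.from_yaml(text)


def _step_sd(config: ExperimentConfig, model: models.ModelSpec):
    if model.name == "oscillator":
        all_masses = set(config.train_on) >= {"x1", "x2", "x3"}
        return inference.oscillator_step_sd(model, all_masses=all_masses)
    return 0.2


def run_experiment(
    config: ExperimentConfig,
    out_dir,
    scale: float | None = None,
    seed: int | None = None,
) -> dict:
    """Run one preset end to end and write its report bundle.

    Returns a dict with the in-memory artefacts (measurements, posterior,
    bands, spectrum, diagnostics).  Any stage failure raises with a
    stage-tagged message; artefacts written before the failure are kept.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scale = config.scale_factor if scale is None else scale
    seed = config.seed if seed is None else seed
    stage = "scenario"
    try:
        gen_model, protocol, measurements = synthetic.make_training_scenario(config.scenario)
        measurements.to_csv(out / "measurements.csv")
        t_grid = models.default_t_grid(gen_model)
        nominal_traj = models.simulate(gen_model, gen_model.nominal, protocol, t_grid)
        nominal_traj.to_csv(out / "nominal_training_trajectory.csv")
        result = {"measurements": measurements, "config": config}
        if not config.train_on:
            (out / "summary.txt").write_text(
                f"preset {config.name}: data-only preset; no training stage\n"
            )
            return result

        stage = "training"
        train_model = models.get_model(config.model)
        mcfg = inference.MCMCConfig(
            n_chains=config.n_chains,
            step_sd=_step_sd(config, train_model),
            seed=seed,
            scale_factor=scale,
        )
        posterior = inference.run_training(
            train_model, measurements, config.train_on, config=mcfg, protocol=protocol
        )
        posterior.to_csv(out / "posterior.csv")
        result["posterior"] = posterior

        stage = "prediction"
        bands = {}
        train_band = analysis.predict_band(
            posterior, train_model, protocol, t_grid, level=config.level
        )
        train_band.to_csv(out / "band_train_protocol.csv")
        bands[protocol.name] = train_band
        for pname in config.protocols:
            proto = models.get_protocol(pname)
            band = analysis.predict_band(
                posterior, train_model, proto, t_grid, level=config.level
            )
            band.to_csv(out / f"band_{pname}.csv")
            bands[pname] = band
            ref = models.simulate(gen_model, gen_model.nominal, proto, t_grid)
            ref.to_csv(out / f"nominal_{pname}.csv")
        result["bands"] = bands

        stage = "perturbation"
        for pert in config.perturbations:
            pname, factor = pert["parameter"], float(pert["factor"])
            for proto_name in config.protocols or [protocol.name]:
                proto = models.get_protocol(proto_name)
                band = analysis.perturb_and_predict(
                    posterior, train_model, proto, pname, factor, t_grid,
                    level=config.level,
                )
                tag = f"{pname}_x{factor:g}".replace(".", "p")
                band.to_csv(out / f"band_{proto_name}_{tag}.csv")
                pert_params = dict(gen_model.nominal)
                if pname in pert_params:
                    pert_params[pname] *= factor
                ref = models.simulate(gen_model, pert_params, proto, t_grid)
                ref.to_csv(out / f"nominal_{proto_name}_{tag}.csv")

        stage = "pca"
        spectrum = analysis.deviation_spectrum(posterior)
        spectrum.to_frame().to_csv(out / "deviation_spectrum.csv")
        result["spectrum"] = spectrum

        stage = "report"
        diag = posterior.diagnostics
        lines = [
            f"preset: {config.name}",
            f"description: {config.description}",
            f"model: {config.model}  trained on: {','.join(config.train_on)}",
            f"scale_factor: {scale}  seed: {seed}  retained samples: {len(posterior.df)}",
            "acceptance rates: " + " ".join(f"{a:.3f}" for a in diag["acceptance"]),
            "max R-hat: %.4f" % max(diag["rhat"].values()),
            "min ESS: %.0f" % min(diag["ess"].values()),
            "deviations delta_i: " + " ".join(f"{d:.2f}" for d in spectrum.deviations),
            f"stiff directions (delta < {analysis.STIFF_THRESHOLD}): "
            f"{analysis.count_stiff(spectrum)}",
        ]
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
        return result
    except Exception as exc:
        raise RuntimeError(f"preset {config.name!r} failed at stage {stage!r}: {exc}") from exc
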