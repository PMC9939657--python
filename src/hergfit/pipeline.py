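"""End-to-end orchestration: generate -> train -> benchmark.

One config drives every stage with a single root seed; each stage writes
its artifact plus a JSON manifest so reruns are reproducible and
intermediate artifacts are reusable (rerunning with an existing dataset
file leaves its checksum untouched).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import dataset as ds_mod
from . import regressor as reg_mod
from .dataset import NoiseModel, generate_dataset, load_dataset, save_dataset
from .inference import BenchmarkReport, CmaesConfig, benchmark_inits
from .model import ChannelParams
from .priors import DEFAULT_PRIOR, NormalizationSpec, PriorSpec
from .protocol import VoltageProtocol, build_default_staircase, read_protocol_csv
from .regressor import RegressorConfig, StageSpec, TrainedRegressor

log = logging.getLogger("hergfit.pipeline")


@dataclass
class PipelineConfig:
    workdir: str = "hergfit-run"
    seed: int = 0
    n_train: int = 500
    n_val: int = 50
    n_cells: int = 10
    protocol_csv: str | None = None      # None -> built-in staircase
    prior: PriorSpec = field(default_factory=PriorSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    downsample_factor: int = 50
    sample_rate: float = 5000.0
    regressor: RegressorConfig = field(default_factory=RegressorConfig)
    fit: CmaesConfig = field(default_factory=CmaesConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "prior" in d and isinstance(d["prior"], dict):
            d["prior"] = PriorSpec(**{k: tuple(v) if isinstance(v, list) else v
                                      for k, v in d["prior"].items()})
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        if "regressor" in d and isinstance(d["regressor"], dict):
            rd = dict(d["regressor"])
            if "stage_schedule" in rd:
                rd["stage_schedule"] = tuple(
                    StageSpec(resolution=tuple(s["resolution"]),
                              n_examples=s.get("n_examples"), epochs=s["epochs"])
                    for s in rd["stage_schedule"]
                )
            for key in ("input_resolution", "pool_grid", "hidden_layers"):
                if key in rd:
                    rd[key] = tuple(rd[key])
            if isinstance(rd.get("stft"), dict):
                from .features import StftParams
                rd["stft"] = StftParams(**rd["stft"])
            d["regressor"] = RegressorConfig(**rd)
        if "fit" in d and isinstance(d["fit"], dict):
            d["fit"] = CmaesConfig(**d["fit"])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Read a pipeline config from YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        return PipelineConfig.from_dict(yaml.safe_load(text))
    return PipelineConfig.from_dict(json.loads(text))


def _protocol(config: PipelineConfig) -> VoltageProtocol:
    if config.protocol_csv:
        return read_protocol_csv(config.protocol_csv)
    return build_default_staircase()


def run_end_to_end(config: PipelineConfig) -> BenchmarkReport:
    """Execute all stages; returns the benchmark report.

    Stage isolation: the dataset file is regenerated only if absent, so
    deleting the model file and rerunning retrains without touching the
    dataset checksum.
    """
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    protocol = _protocol(config)

    # --- stage 1: dataset -------------------------------------------------
    data_path = work / "data.h5"
    stage = "dataset"
    try:
        if data_path.exists():
            log.info("[dataset] reusing %s", data_path)
            full = load_dataset(data_path)
        else:
            log.info("[dataset] generating %d+%d examples (seed %d)",
                     config.n_train, config.n_val, config.seed)
            full = generate_dataset(
                config.n_train + config.n_val, spec=config.prior, protocol=protocol,
                noise=config.noise, factor=config.downsample_factor,
                seed=config.seed, sample_rate=config.sample_rate,
            )
            save_dataset(full, data_path)
        train_ds = reg_mod._subset(full, config.n_train)
        val_ds = ds_mod.Dataset(
            traces=full.traces[config.n_train:], targets=full.targets[config.n_train:],
            theta=full.theta[config.n_train:], manifest=dict(full.manifest),
        )

        # --- stage 2: regressor -------------------------------------------
        stage = "train"
        model_path = work / "model.bin"
        if model_path.exists():
            log.info("[train] reusing %s", model_path)
            model = reg_mod.load(model_path)
        else:
            log.info("[train] %d examples, %d stages", len(train_ds),
                     len(config.regressor.stage_schedule))
            model = reg_mod.train(config.regressor, train_ds, val_ds)
            reg_mod.save(model, model_path)

        # --- stage 3: benchmark cells -------------------------------------
        stage = "benchmark"
        cells_ds = generate_dataset(
            config.n_cells, spec=config.prior, protocol=protocol,
            noise=config.noise, factor=config.downsample_factor,
            seed=(config.seed + 99_991) % (2**31), sample_rate=config.sample_rate,
        )
        cells = [(cells_ds.example(i).trace, cells_ds.example(i).theta_raw)
                 for i in range(len(cells_ds))]
        report = benchmark_inits(cells, model, protocol, spec=config.prior,
                                 config=config.fit, seed=config.seed)
        summary = report.summary()
        (work / "report.json").write_text(json.dumps({
            "seed": config.seed,
            "dataset_checksum": full.checksum(),
            "summary": summary,
        }, indent=2))
        log.info("[benchmark] %s", summary)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed ({work})") from exc
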