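"""End-to-end run: classify -> estimate -> compare, with a run manifest.

A run reads one sample CSV, writes the food-web assignments, per-individual
TP estimates, species summary and regression report into an output
directory, and finishes with a JSON manifest listing every output with a
SHA-256 checksum plus the constants and seeds used. Warnings (anomalous
bulk values, bulk-only samples, species excluded from the ANOVA) go to the
log and into the manifest. On any stage error the partial outputs created
by the run are removed and the error is re-raised.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .baseline import ClassifierConfig, class_counts, classify_dataset, config_from_mapping
from .compare import anova_tukey, bulk_vs_tp_regression, comparison_to_records
from .errors import AminotpError, ValidationError
from .samples import Dataset, read_samples, write_results
from .tp import DEFAULT_MC_DRAWS, Method, TDFParams, estimate_dataset, estimates_to_records

logger = logging.getLogger("aminotp")


@dataclasses.dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    input_path: str
    config_path: str | None
    config_sha256: str | None
    seed: int | None
    method: str
    constants: dict
    outputs: dict[str, str]  # relative path -> sha256
    warnings: list[str]
    version: str
    started_utc: str
    finished_utc: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _utc(ts: float) -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime(ts))


class _JsonLineHandler(logging.Handler):
    def __init__(self, path: Path):
        super().__init__()
        self._fh = path.open("a")

    def emit(self, record: logging.LogRecord) -> None:
        self._fh.write(
            json.dumps(
                {"t": record.created, "level": record.levelname, "msg": record.getMessage()}
            )
            + "\n"
        )
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()
        super().close()


def load_run_config(path: str | Path | None) -> dict:
    """Flat YAML config shared by all stages; empty dict if no file given."""
    if path is None:
        return {}
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: run config must be a mapping")
    return raw


def run_all(
    samples_path: str | Path,
    out_dir: str | Path,
    *,
    config_path: str | Path | None = None,
    seed: int | None = None,
    method: Method | str = Method.TAYLOR_FIRST_ORDER,
    n_draws: int = DEFAULT_MC_DRAWS,
    alpha: float = 0.05,
    exclude_from_regression: tuple[str, ...] = ("MARINE",),
) -> RunManifest:
    """Run the whole pipeline on one sample table.

    Outputs written into `out_dir`: assignments.csv, tp_results.csv,
    species_summary.csv, regression.json, run.log (JSON lines) and
    manifest.json. The comparison stages are skipped with a notice when the
    data cannot support them (no AA samples, or fewer than two species).
    """
    started = time.time()
    samples_path = Path(samples_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    method = Method(method)

    raw_cfg = load_run_config(config_path)
    classifier = config_from_mapping(raw_cfg)
    tdf = TDFParams(
        mean=float(raw_cfg.get("tdf_mean", 7.6)),
        sigma=float(raw_cfg.get("tdf_sigma", 1.2)),
    )
    alpha = float(raw_cfg.get("alpha", alpha))

    log_path = out_dir / "run.log"
    handler = _JsonLineHandler(log_path)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    created: list[Path] = [log_path]
    warnings: list[str] = []
    outputs: dict[str, str] = {}

    def emit(path: Path, rows) -> None:
        write_results(path, rows)
        created.append(path)

    try:
        ds = read_samples(samples_path)
        logger.info("read %d samples from %s", len(ds), samples_path)

        assignments = classify_dataset(ds, config=classifier)
        counts = class_counts(assignments)
        logger.info("class counts: %s", {k.value: v for k, v in counts.items()})
        for a in assignments:
            if a.anomaly_flag:
                msg = f"sample {a.sample_id!r}: bulk values outside the observed cluster regions"
                warnings.append(msg)
                logger.warning(msg)
        emit(
            out_dir / "assignments.csv",
            [
                {
                    "sample_id": a.sample_id,
                    "food_web": a.food_web.label.value,
                    "beta_mean": a.food_web.beta_mean,
                    "beta_sigma": a.food_web.beta_sigma,
                    "rule_fired": a.rule_fired.value,
                    "anomaly_flag": a.anomaly_flag,
                }
                for a in assignments
            ],
        )

        estimates, notices = estimate_dataset(
            ds, assignments, tdf, method=method, n_draws=n_draws, seed=seed
        )
        for msg in notices:
            warnings.append(msg)
            logger.warning(msg)
        if estimates:
            emit(out_dir / "tp_results.csv", estimates_to_records(estimates))
        else:
            msg = "no amino-acid-measured samples: TP estimation produced no results"
            warnings.append(msg)
            logger.warning(msg)

        n_species = len({e.species for e in estimates})
        if estimates and n_species >= 2:
            cmp = anova_tukey(estimates, alpha=alpha)
            for sp in cmp.excluded_species:
                msg = f"species {sp!r} has < 2 estimates; excluded from ANOVA"
                warnings.append(msg)
                logger.warning(msg)
            emit(out_dir / "species_summary.csv", comparison_to_records(cmp))

            bulk = {s.sample_id: s.d15n_bulk for s in ds}
            table = [
                {
                    "sample_id": e.sample_id,
                    "tp_mean": e.tp_mean,
                    "d15n_bulk": bulk[e.sample_id],
                    "food_web": e.food_web_label,
                }
                for e in estimates
            ]
            import pandas as pd

            reg = bulk_vs_tp_regression(pd.DataFrame(table), exclude=exclude_from_regression)
            reg_path = out_dir / "regression.json"
            reg_path.write_text(
                json.dumps(
                    {
                        "slope": reg.slope,
                        "intercept": reg.intercept,
                        "r_squared": reg.r_squared,
                        "p_value": reg.p_value,
                        "n": reg.n,
                        "excluded_labels": reg.excluded_labels,
                        "excluded_ids": reg.excluded_ids,
                        "anova_F": None if math.isinf(cmp.anova_F) else cmp.anova_F,
                        "anova_p": cmp.anova_p,
                    },
                    indent=2,
                )
            )
            created.append(reg_path)
        else:
            msg = "fewer than two species with TP estimates: comparison stage skipped"
            warnings.append(msg)
            logger.warning(msg)

        for path in created:
            if path.name != "run.log":
                outputs[path.name] = _sha256(path)

        manifest = RunManifest(
            input_path=str(samples_path),
            config_path=str(config_path) if config_path else None,
            config_sha256=_sha256(Path(config_path)) if config_path else None,
            seed=seed,
            method=method.value,
            constants={
                "tdf_mean": tdf.mean,
                "tdf_sigma": tdf.sigma,
                "alpha": alpha,
                "betas": {k.value: list(v) for k, v in classifier.betas.items()},
                "thresholds": {
                    "d13c_marine": classifier.d13c_marine,
                    "d15n_marine": classifier.d15n_marine,
                    "d13c_c4": classifier.d13c_c4,
                    "d15n_c4": classifier.d15n_c4,
                },
            },
            outputs=outputs,
            warnings=warnings,
            version=__version__,
            started_utc=_utc(started),
            finished_utc=_utc(time.time()),
        )
        (out_dir / "manifest.json").write_text(manifest.to_json())
        logger.info("run complete: %d output file(s)", len(outputs))
        return manifest
    except AminotpError:
        for path in created:
            if path.exists() and path.name != "run.log":
                path.unlink()
        logger.exception("run failed; partial outputs removed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
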