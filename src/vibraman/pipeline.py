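"""End-to-end orchestration: validated config, staged run, reproducible manifest.

The pipeline ties the stages together: read mode tables, synthesize the
theoretical spectrum, bin/average/normalize the experimental spectra, detect
bands, match modes to bands, select biomarker candidates, and write an
overlay report.  Outputs are plain TSV plus a JSON manifest carrying the full
config echo, input/output checksums and the seed, so identical config and
inputs reproduce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .band_matching import (
    detect_bands,
    estimate_shift,
    match_modes_to_bands,
    overlay_report,
    select_biomarkers,
)
from .errors import VibramanError
from .exp_preprocess import (
    BinnedSpectrum,
    GridSpec,
    average_replicates,
    bin_spectrum,
    normalize_to_100,
    write_binned_tsv,
)
from .fragment_assign import attribution_from_table
from .spectra_model import (
    IntensityParams,
    LineshapeParams,
    ScalingModel,
    fixture_spectrum,
    synthesize_spectrum,
)
from .vib_io import read_freqjob_log, read_mode_table_tsv, read_spectrum_txt

logger = logging.getLogger(__name__)


class ScalingConfig(BaseModel):
    apply: bool = True
    a: float = -0.0000083526
    b: float = 0.98134


class IntensityConfig(BaseModel):
    nu0: float = 1.0e7 / 532.0
    temperature: float = Field(298.15, gt=0)
    f: float | None = Field(None, gt=0, description="None = normalize spectrum max to 100")


class LineshapeConfig(BaseModel):
    fwhm: float = Field(5.0, gt=0)
    grid_min: float = 400.0
    grid_max: float = 1800.0
    grid_step: float = Field(0.5, gt=0)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.grid_min < self.grid_max:
            raise ValueError("lineshape grid_min must be < grid_max")
        return self


class PreprocessConfig(BaseModel):
    grid_start: float = 400.0
    grid_stop: float = 1800.0
    grid_step: float = Field(5.0, gt=0)
    normalize: bool = True
    average_replicates: bool = True
    #: averaging happens before normalization by default; set False to
    #: normalize each replicate first
    average_before_normalize: bool = True

    @model_validator(mode="after")
    def _ordered(self):
        if not self.grid_start < self.grid_stop:
            raise ValueError("preprocessing grid_start must be < grid_stop")
        return self

    def grid(self) -> GridSpec:
        return GridSpec(self.grid_start, self.grid_stop, self.grid_step)


class MatchingConfig(BaseModel):
    tolerance: float = Field(10.0, gt=0)
    prominence_fraction: float = Field(0.05, gt=0, lt=1)


class SelectionConfig(BaseModel):
    region_start: float = 400.0
    region_stop: float = 1800.0
    override_path: str | None = None

    @model_validator(mode="after")
    def _ordered(self):
        if not self.region_start < self.region_stop:
            raise ValueError("selection region_start must be < region_stop")
        return self


class RunConfig(BaseModel):
    """Every tunable that affects pipeline output, validated up front."""

    theory_mode: Literal["fixture", "eq2"] = "fixture"
    scaling: ScalingConfig = ScalingConfig()
    intensity: IntensityConfig = IntensityConfig()
    lineshape: LineshapeConfig = LineshapeConfig()
    preprocessing: PreprocessConfig = PreprocessConfig()
    matching: MatchingConfig = MatchingConfig()
    selection: SelectionConfig = SelectionConfig()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_modes(path: Path):
    if path.suffix.lower() in (".log", ".out"):
        return read_freqjob_log(path)
    return read_mode_table_tsv(path)


def run_pipeline(
    config: RunConfig,
    mode_files: Sequence[str | Path],
    spectrum_files: Sequence[str | Path],
    out_dir: str | Path,
) -> Path:
    """Run every stage and write TSV outputs plus ``manifest.json``.

    Any stage error aborts with the stage name; partial outputs written so
    far are preserved in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    stage_log: list[str] = []
    outputs: dict[str, str] = {}

    def _done(name: str, path: Path) -> None:
        outputs[name] = _sha256(path)
        stage_log.append(f"{stage}: wrote {path.name}")

    try:
        stage = "read-modes"
        tables = [_load_modes(Path(p)) for p in mode_files]
        if not tables:
            raise VibramanError("at least one mode file is required")

        stage = "theory"
        shape = LineshapeParams(
            fwhm=config.lineshape.fwhm,
            grid_min=config.lineshape.grid_min,
            grid_max=config.lineshape.grid_max,
            grid_step=config.lineshape.grid_step,
        )
        scaling = ScalingModel(config.scaling.a, config.scaling.b) if config.scaling.apply else None
        params = IntensityParams(
            nu0=config.intensity.nu0,
            temperature=config.intensity.temperature,
            f=config.intensity.f,
        )
        for table in tables:
            if config.theory_mode == "fixture":
                spectrum = fixture_spectrum(table, shape)
            else:
                spectrum = synthesize_spectrum(table, scaling, params, shape)
            path = out_dir / f"theory_{_slug(table.complex_name)}.tsv"
            with path.open("w", encoding="utf-8") as fh:
                fh.write("wavenumber\tintensity\n")
                for w, y in zip(spectrum.grid, spectrum.intensities):
                    fh.write(f"{w:g}\t{y:.8g}\n")
            _done(f"theory_{table.complex_name}", path)

        stage = "preprocess"
        grid = config.preprocessing.grid()
        binned: list[BinnedSpectrum] = []
        for p in spectrum_files:
            raw = read_spectrum_txt(Path(p))
            binned.append(bin_spectrum(raw, grid))
        processed: list[BinnedSpectrum] = []
        if binned:
            if config.preprocessing.average_replicates and len(binned) > 1:
                if config.preprocessing.average_before_normalize:
                    averaged = average_replicates(binned, label="averaged")
                    processed = [normalize_to_100(averaged)
                                 if config.preprocessing.normalize else averaged]
                else:
                    normed = [normalize_to_100(b) for b in binned]
                    processed = [average_replicates(normed, label="averaged")]
            else:
                processed = [normalize_to_100(b) if config.preprocessing.normalize else b
                             for b in binned]
            for spec in processed:
                path = out_dir / f"binned_{_slug(spec.label)}.tsv"
                write_binned_tsv(spec, path)
                _done(f"binned_{spec.label}", path)

        stage = "match"
        all_matches = []
        shifts: dict[str, float] = {}
        if processed:
            for table in tables:
                for spec in processed:
                    bands = detect_bands(spec, config.matching.prominence_fraction)
                    matches = match_modes_to_bands(
                        table.modes, bands, config.matching.tolerance, source_label=spec.label
                    )
                    all_matches.extend(matches)
                    if matches:
                        shifts[f"{table.complex_name}|{spec.label}"] = estimate_shift(matches)
                    path = out_dir / f"matches_{_slug(table.complex_name)}_{_slug(spec.label)}.tsv"
                    with path.open("w", encoding="utf-8") as fh:
                        fh.write("mode_index\tmode_wavenumber\tband_wavenumber\tshift\tsource\n")
                        for m in matches:
                            fh.write(f"{m.mode_index}\t{m.mode_wavenumber:g}\t"
                                     f"{m.band_wavenumber:g}\t{m.shift:g}\t{m.source_label}\n")
                    _done(f"matches_{table.complex_name}_{spec.label}", path)

        stage = "biomarkers"
        include: list[int] = []
        exclude: list[int] = []
        if config.selection.override_path:
            override = json.loads(Path(config.selection.override_path).read_text())
            include = list(override.get("include", []))
            exclude = list(override.get("exclude", []))
        region = GridSpec(config.selection.region_start, config.selection.region_stop,
                          config.preprocessing.grid_step)
        for table in tables:
            attributions = attribution_from_table(table)
            candidates = select_biomarkers(
                table, attributions, all_matches, region, include=include, exclude=exclude
            )
            report = overlay_report(table, processed, candidates)
            path = out_dir / f"biomarkers_{_slug(table.complex_name)}.tsv"
            report.to_csv(path, sep="\t", index=False)
            _done(f"biomarkers_{table.complex_name}", path)

        stage = "manifest"
        manifest = {
            "vibraman_version": __version__,
            "config": config.model_dump(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "inputs": {str(p): _sha256(Path(p)) for p in [*mode_files, *spectrum_files]},
            "outputs": outputs,
            "estimated_shifts": shifts,
            "stages": stage_log,
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        logger.error("pipeline aborted in stage %r: %s", stage, exc)
        raise VibramanError(f"stage {stage!r} failed: {exc}") from exc
    return out_dir


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "-" for c in text.strip().lower())
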