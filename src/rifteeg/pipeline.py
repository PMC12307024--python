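"""End-to-end orchestration of the simulated tagging experiment.

``run_pipeline`` executes the stages in their scientific order:

1. simulate the dataset (one EpochSet per participant);
2. optional zero-phase filtering;
3. baseline and tagging power spectra (1-80 Hz, 1 Hz steps) and the
   percent power change;
4. tagging-vs-baseline cluster permutation tests at the two base
   frequencies and the difference intermodulation frequency, with the
   conditions combined;
5. *gated* condition contrasts: the related-vs-unrelated comparison at a
   frequency is computed only if the tagging-vs-baseline test at that
   frequency was significant — at the base frequencies as a cluster test
   on the percent change, at the intermodulation frequency via the
   electrode-selection procedure;
6. the two validation tables for the selection procedure.

Every statistic in the report is reproducible from the config and seed
alone; the expensive spectral stage is computed once and shared by all
frequencies. Artifacts are written as a JSON report plus TSV tables with
a manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import ClusterTestResult, cluster_test
from .preprocess import bandpass_notch
from .selection import (SelectionResult, base_frequency_validation,
                        neighbor_frequency_validation, selection_contrast)
from .simulate import SimConfig, simulate_dataset
from .spectral import (PercentChangeMap, SpectrumSet, intermodulation_freqs,
                       percent_change, windowed_power)

__all__ = ["AnalysisConfig", "RunReport", "run_pipeline", "load_run_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the statistical stages."""

    n_perm: int = 5000
    alpha: float = 0.05
    alpha_form: float = 0.05
    k: int = 6
    f_lo: float = 1.0
    f_hi: float = 80.0
    apply_filter: bool = False
    filter_low: float = 0.1
    filter_high: float = 100.0
    filter_notches: tuple[float, ...] = (50.0, 100.0, 150.0)


@dataclass
class RunReport:
    """Everything one pipeline run computed, JSON-serializable."""

    sim_config: dict
    analysis_config: dict
    version: str
    baseline_vs_tagging: dict[float, ClusterTestResult]
    condition_contrasts: dict[float, ClusterTestResult | None]
    selection: SelectionResult | None
    neighbor_validation: pd.DataFrame
    base_validation: pd.DataFrame
    spectra: dict[str, SpectrumSet] = field(default=None, repr=False)
    percent_change: PercentChangeMap = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "sim_config": self.sim_config,
            "analysis_config": self.analysis_config,
            "baseline_vs_tagging": {
                str(f): r.to_dict(frequency_hz=f, contrast="tagging_vs_baseline")
                for f, r in self.baseline_vs_tagging.items()},
            "condition_contrasts": {
                str(f): (None if r is None else
                         r.to_dict(frequency_hz=f, contrast="related_vs_unrelated"))
                for f, r in self.condition_contrasts.items()},
            "selection": None if self.selection is None else self.selection.to_dict(),
            "neighbor_validation": self.neighbor_validation.to_dict("records"),
            "base_validation": self.base_validation.rename(columns=str)
                                   .reset_index().to_dict("records"),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {}
        (out / "report.json").write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True))
        files["report.json"] = "full statistical report"
        for name, spec in (self.spectra or {}).items():
            fn = f"power_{name}.tsv"
            spec.to_frame().to_csv(out / fn, sep="\t", index=False)
            files[fn] = f"{name}-window power spectra (long format)"
        if self.percent_change is not None:
            self.percent_change.to_frame().to_csv(
                out / "percent_change.tsv", sep="\t", index=False)
            files["percent_change.tsv"] = "percent power change (long format)"
        if self.selection is not None:
            self.selection.mean_pc.to_csv(out / "selection_means.tsv", sep="\t")
            files["selection_means.tsv"] = \
                "per-participant selected-cluster mean percent change"
        (out / "manifest.json").write_text(json.dumps(files, indent=1,
                                                      sort_keys=True))


def _combined_power_at(spec: SpectrumSet, freq: float) -> np.ndarray:
    """(participant, electrode) power at one frequency, conditions averaged."""
    return spec.power[:, :, :, spec.freq_index(freq)].mean(axis=1)


def _pc_by_condition(pc: PercentChangeMap, freq: float) -> tuple[np.ndarray, np.ndarray]:
    fi = pc.freq_index(freq)
    ri = pc.conditions.index("related")
    ui = pc.conditions.index("unrelated")
    return pc.pc[:, ri, :, fi], pc.pc[:, ui, :, fi]


def run_pipeline(sim_cfg: SimConfig,
                 analysis: AnalysisConfig | None = None,
                 out_dir: str | Path | None = None) -> RunReport:
    """Run the whole simulated experiment and its statistics."""
    analysis = analysis or AnalysisConfig()
    dataset = simulate_dataset(sim_cfg)
    if analysis.apply_filter:
        dataset = [bandpass_notch(e, analysis.filter_low, analysis.filter_high,
                                  analysis.filter_notches) for e in dataset]
    baseline = windowed_power(dataset, "baseline", analysis.f_lo, analysis.f_hi)
    tagging = windowed_power(dataset, "tagging", analysis.f_lo, analysis.f_hi)
    pc = percent_change(tagging, baseline)
    montage = sim_cfg.montage

    im = intermodulation_freqs(sim_cfg.tag.f_audio, sim_cfg.tag.f_visual)
    freqs = (sim_cfg.tag.f_audio, sim_cfg.tag.f_visual, im["difference"])
    # independent permutation streams per analysis, all derived from the seed
    streams = np.random.SeedSequence(sim_cfg.seed ^ 0x5EED).spawn(2 * len(freqs))

    base_vs_tag: dict[float, ClusterTestResult] = {}
    cond: dict[float, ClusterTestResult | None] = {}
    selection = None
    for i, f in enumerate(freqs):
        base_vs_tag[f] = cluster_test(
            _combined_power_at(tagging, f), _combined_power_at(baseline, f),
            montage, n_perm=analysis.n_perm, alpha=analysis.alpha,
            rng=np.random.default_rng(streams[2 * i]),
            alpha_form=analysis.alpha_form)
        gate_open = base_vs_tag[f].any_significant
        if f == im["difference"]:
            if gate_open:
                selection = selection_contrast(pc, montage, freq=f, k=analysis.k)
        else:
            cond[f] = None
            if gate_open:
                a, b = _pc_by_condition(pc, f)
                cond[f] = cluster_test(
                    a, b, montage, n_perm=analysis.n_perm, alpha=analysis.alpha,
                    rng=np.random.default_rng(streams[2 * i + 1]),
                    alpha_form=analysis.alpha_form)

    neighbor = neighbor_frequency_validation(pc, montage, k=analysis.k)
    base_val = base_frequency_validation(
        pc, montage, k=analysis.k,
        freqs=(sim_cfg.tag.f_audio, sim_cfg.tag.f_visual))

    sim_dict = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in asdict(sim_cfg).items()
                if k not in ("montage", "tag")}
    sim_dict["tag"] = asdict(sim_cfg.tag)
    report = RunReport(sim_config=sim_dict, analysis_config=asdict(analysis),
                       version=__version__, baseline_vs_tagging=base_vs_tag,
                       condition_contrasts=cond, selection=selection,
                       neighbor_validation=neighbor, base_validation=base_val,
                       spectra={"baseline": baseline, "tagging": tagging},
                       percent_change=pc)
    if out_dir is not None:
        report.write(out_dir)
    return report


def load_run_config(path: str | Path) -> tuple[SimConfig, AnalysisConfig]:
    """Load a YAML/JSON run config with 'simulation' and 'analysis' sections."""
    from .io import _CFG_FIELDS, _TAG_FIELDS  # local import to avoid a cycle
    from .simulate import TagConfig

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    sim_raw = raw.get("simulation", {})
    if "seed" not in sim_raw:
        raise ValueError("simulation section must specify an integer 'seed'")
    kwargs = {k: sim_raw[k] for k in _CFG_FIELDS if k in sim_raw}
    if "tag" in sim_raw:
        kwargs["tag"] = TagConfig(**{k: sim_raw["tag"][k] for k in _TAG_FIELDS
                                     if k in sim_raw["tag"]})
    for name in ("topo_audio", "topo_visual", "topo_im"):
        if sim_raw.get(name) is not None:
            kwargs[name] = np.asarray(sim_raw[name], dtype=float)
    ana_raw = dict(raw.get("analysis", {}))
    if "filter_notches" in ana_raw:
        ana_raw["filter_notches"] = tuple(ana_raw["filter_notches"])
    return SimConfig(**kwargs), AnalysisConfig(**ana_raw)
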