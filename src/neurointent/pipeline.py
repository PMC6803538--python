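"""End-to-end orchestration: configuration, provenance, staged execution.

``run_pipeline`` executes simulate -> preprocess -> sensorstats -> nvc ->
network -> classify, writing each stage's artifacts under the output root in
the native TSV/JSON format and recording a provenance file (config hash,
seed, checksums, timestamps).  Completed stages with intact checksums are
skipped on re-runs; corrupted intermediates raise with the offending file
named.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as nio
from . import nvc as nvc_mod
from .classify import IntentionDecoder, fuse, repeated_cv
from .network import feature_table, grand_average_networks
from .paradigm import ConfigurationError, ParadigmConfig, build_schedule
from .preprocessing import PreprocessingConfig, preprocess_eeg, preprocess_fnirs
from .sensor_stats import channel_anova, grand_average, hbo_block_ttest
from .synth import (
    GeneratorConfig,
    SyntheticGroundTruth,
    default_ground_truth,
    generate_eeg,
    generate_fnirs,
    RawRecording,
)
from . import layouts

__version__ = "0.1.0"


@dataclass(frozen=True)
class NetworkConfig:
    density: float = 0.3
    window_s: tuple[float, float] = (0.0, 3.5)
    fnirs_band_hz: tuple[float | None, float | None] = (0.01, 2.0)


@dataclass(frozen=True)
class NvcConfig:
    threshold: float = 0.8
    fnirs_band_hz: tuple[float | None, float | None] = (0.01, None)
    x_ms: tuple[int, int, int] = (100, 600, 1)  # start, stop, step
    y_ms: tuple[int, int, int] = (0, 3000, 27)


@dataclass(frozen=True)
class ClassifyConfig:
    n_keep: int = 60
    k_neighbors: int = 10
    n_reps: int = 10
    n_folds: int = 10
    c_exponents: tuple[int, int, int] = (-5, 15, 2)  # start, stop, step (2**e)
    gamma_exponents: tuple[int, int, int] = (-15, 3, 2)
    inner_folds: int = 5

    def c_grid(self) -> tuple[float, ...]:
        a, b, s = self.c_exponents
        return tuple(2.0**e for e in range(a, b + 1, s))

    def gamma_grid(self) -> tuple[float, ...]:
        a, b, s = self.gamma_exponents
        return tuple(2.0**e for e in range(a, b + 1, s))


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; strictly validated from YAML."""

    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    nvc: NvcConfig = field(default_factory=NvcConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    effect_size: float = 1.0
    nvc_lag_ms: float = 1700.0
    seed: int = 0

    def ground_truth(self) -> SyntheticGroundTruth:
        return default_ground_truth(self.effect_size, self.nvc_lag_ms)


_SUBCONFIGS = {
    "paradigm": ParadigmConfig,
    "generator": GeneratorConfig,
    "preprocessing": PreprocessingConfig,
    "network": NetworkConfig,
    "nvc": NvcConfig,
    "classify": ClassifyConfig,
}


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    data = dict(data or {})
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ConfigurationError(f"unknown top-level config key(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SUBCONFIGS.items():
        if name in data:
            sub = data.pop(name)
            if not isinstance(sub, dict):
                raise ConfigurationError(f"{name} must be a mapping")
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(sub) - sub_fields
            if bad:
                raise ConfigurationError(
                    f"unknown key(s) {sorted(bad)} in section {name!r}"
                )
            # YAML lists -> tuples where the dataclass expects tuples
            sub = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
            }
            kwargs[name] = cls(**sub)
    kwargs.update(data)
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _dir_checksums(path: Path) -> dict[str, str]:
    return {
        str(p.relative_to(path)): _checksum(p)
        for p in sorted(path.rglob("*"))
        if p.is_file()
    }


class StageError(RuntimeError):
    pass


@dataclass
class ProvenanceRecord:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 resume: bool = True) -> ProvenanceRecord:
    """Run every stage, writing artifacts and provenance under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov_path = out / "provenance.json"
    prov = ProvenanceRecord(config_hash(config), config.seed, __version__)
    prior = None
    if resume and prov_path.exists():
        prior = json.loads(prov_path.read_text())
        if prior.get("config_hash") != prov.config_hash:
            prior = None

    def stage(name: str, fn) -> Path:
        stage_dir = out / name
        if prior and name in prior.get("stages", {}):
            recorded = prior["stages"][name]["checksums"]
            actual = _dir_checksums(stage_dir) if stage_dir.exists() else {}
            if recorded == actual:
                prov.stages[name] = prior["stages"][name]
                return stage_dir
            mismatched = sorted(
                set(recorded) ^ set(actual)
                | {k for k in set(recorded) & set(actual) if recorded[k] != actual[k]}
            )
            raise StageError(
                f"stage {name!r}: on-disk artifacts do not match provenance "
                f"(files: {mismatched[:5]}); delete {stage_dir} to recompute"
            )
        t0 = time.time()
        try:
            fn(stage_dir)
        except Exception as err:
            raise StageError(f"stage {name!r} failed: {err}") from err
        prov.stages[name] = {
            "checksums": _dir_checksums(stage_dir),
            "elapsed_s": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        prov.save(prov_path)
        return stage_dir

    truth = config.ground_truth()
    schedule = build_schedule(config.paradigm)
    eeg_names, eeg_xy = layouts.standard_64_layout()
    f_names, _ = layouts.fnirs_parietal_layout()

    def do_simulate(d: Path) -> None:
        ss = np.random.SeedSequence(config.seed).spawn(2)
        eeg, eog = generate_eeg(
            schedule, truth, config.generator,
            int(ss[0].generate_state(1)[0] % (2**31)),
        )
        intensity = generate_fnirs(
            schedule, truth, config.generator,
            int(ss[1].generate_state(1)[0] % (2**31)),
        )
        rec = RawRecording(
            eeg=eeg, eog=eog, fnirs_intensity=intensity, schedule=schedule,
            ground_truth=truth, generator=config.generator,
            eeg_channel_names=eeg_names, fnirs_channel_names=f_names,
        )
        nio.save_recording(rec, d)

    sim_dir = stage("simulate", do_simulate)
    rec = nio.load_recording(sim_dir)

    def do_preprocess(d: Path) -> None:
        eeg_ep = preprocess_eeg(
            rec.eeg, rec.eog, rec.eeg_rate_hz, rec.schedule,
            config.preprocessing, rec.eeg_channel_names,
        )
        nio.save_epochs(eeg_ep, d / "eeg")
        hb = preprocess_fnirs(
            rec.fnirs_intensity, rec.fnirs_rate_hz, rec.schedule,
            config.preprocessing, rec.generator.wavelengths_nm,
            rec.generator.dpf, channel_names=rec.fnirs_channel_names,
        )
        for name, ep in hb.items():
            nio.save_epochs(ep, d / name.lower())
        # wide-band HbO variants for the network and NVC stages
        for tag, band in (
            ("hbo_network", config.network.fnirs_band_hz),
            ("hbo_nvc", config.nvc.fnirs_band_hz),
        ):
            wide = preprocess_fnirs(
                rec.fnirs_intensity, rec.fnirs_rate_hz, rec.schedule,
                config.preprocessing, rec.generator.wavelengths_nm,
                rec.generator.dpf, band_hz=band,
                channel_names=rec.fnirs_channel_names,
            )["HbO"]
            nio.save_epochs(wide, d / tag)

    pre_dir = stage("preprocess", do_preprocess)
    eeg_ep = nio.load_epochs(pre_dir / "eeg")
    hbo_ep = nio.load_epochs(pre_dir / "hbo")
    hbo_net_ep = nio.load_epochs(pre_dir / "hbo_network")
    hbo_nvc_ep = nio.load_epochs(pre_dir / "hbo_nvc")

    def do_sensorstats(d: Path) -> None:
        d.mkdir(parents=True, exist_ok=True)
        erp_win = tuple(v / 1000.0 for v in truth.erp_window_ms)
        anova_eeg = channel_anova(eeg_ep, erp_win, alpha=0.001)
        anova_hbo = channel_anova(hbo_ep, (0.0, 3.5), alpha=0.05)
        ttests = hbo_block_ttest(hbo_ep)
        import pandas as pd

        pd.DataFrame(
            {
                "channel": eeg_ep.channel_names,
                "F": anova_eeg.statistic,
                "p": anova_eeg.p,
                "significant": anova_eeg.significant,
            }
        ).to_csv(d / "eeg_anova.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "channel": hbo_ep.channel_names,
                "F": anova_hbo.statistic,
                "p": anova_hbo.p,
                "significant": anova_hbo.significant,
            }
        ).to_csv(d / "hbo_anova.tsv", sep="\t", index=False)
        rows = []
        for t, res in ttests.items():
            for ch, (tv, pv) in enumerate(zip(res.statistic, res.p)):
                rows.append(
                    {"time_s": t, "channel": hbo_ep.channel_names[ch],
                     "t": tv, "p": pv}
                )
        pd.DataFrame(rows).to_csv(d / "hbo_ttest.tsv", sep="\t", index=False)

    stage("sensorstats", do_sensorstats)

    def do_nvc(d: Path) -> None:
        d.mkdir(parents=True, exist_ok=True)
        conds_e, ga_e = grand_average(eeg_ep)
        conds_h, ga_h = grand_average(hbo_nvc_ep)
        erp_w = nvc_mod.summary_waveform(ga_e)
        hbo_w = nvc_mod.summary_waveform(ga_h)
        xs, ys = config.nvc.x_ms, config.nvc.y_ms
        surface = nvc_mod.lag_surface(
            erp_w, eeg_ep.times_s, hbo_w, hbo_nvc_ep.times_s, conds_e,
            np.arange(xs[0], xs[1] + 1, xs[2]),
            np.arange(ys[0], ys[1] + 1, ys[2]),
        )
        region = nvc_mod.high_corr_region(surface, config.nvc.threshold)
        np.savetxt(d / "r_min.tsv", surface.r_min, fmt="%.6g", delimiter="\t")
        (d / "report.json").write_text(
            json.dumps(
                {
                    "threshold": region.threshold,
                    "peak_x_ms": region.peak_x_ms,
                    "peak_y_ms": region.peak_y_ms,
                    "peak_r": region.peak_r,
                    "n_region_points": int(region.mask.sum()),
                },
                indent=1,
            )
        )

    stage("nvc", do_nvc)

    def do_network(d: Path) -> None:
        eeg_feat = feature_table(eeg_ep, config.network.window_s,
                                 config.network.density)
        fnirs_feat = feature_table(hbo_net_ep, config.network.window_s,
                                   config.network.density)
        nio.save_features(eeg_feat, d / "eeg")
        nio.save_features(fnirs_feat, d / "fnirs")
        for cond, net in grand_average_networks(
            eeg_ep, config.network.window_s, config.network.density
        ).items():
            nio.save_network(net, d / f"grand_eeg_{cond}")

    net_dir = stage("network", do_network)
    eeg_feat = nio.load_features(net_dir / "eeg")
    fnirs_feat = nio.load_features(net_dir / "fnirs")

    def do_classify(d: Path) -> None:
        d.mkdir(parents=True, exist_ok=True)
        cc = config.classify
        decoder = IntentionDecoder(
            n_keep=cc.n_keep, k_neighbors=cc.k_neighbors,
            c_grid=cc.c_grid(), gamma_grid=cc.gamma_grid(),
            inner_folds=cc.inner_folds, seed=config.seed,
        )
        results = {}
        for name, table in (
            ("eeg", eeg_feat),
            ("fnirs", fnirs_feat),
            ("fused", fuse(eeg_feat, fnirs_feat)),
        ):
            res = repeated_cv(
                table.values, table.labels, cc.n_reps, cc.n_folds,
                decoder, config.seed,
            )
            results[name] = res
            np.savetxt(
                d / f"confusion_{name}.tsv", res.confusion, fmt="%d",
                delimiter="\t",
            )
        import pandas as pd

        pd.DataFrame(
            {
                "modality": list(results),
                "accuracy_pct": [100 * r.mean_accuracy for r in results.values()],
                "sd_pct": [
                    100 * r.accuracies.mean(axis=1).std() for r in results.values()
                ],
            }
        ).to_csv(d / "accuracy.tsv", sep="\t", index=False)
        (d / "selected_features.json").write_text(
            json.dumps(
                {
                    name: [idx.tolist() for idx in res.selected_features[:3]]
                    for name, res in results.items()
                },
                indent=1,
            )
        )

    stage("classify", do_classify)
    prov.save(prov_path)
    return prov
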