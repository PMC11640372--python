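"""File formats, run configuration, and the end-to-end pipeline.

CSV for HR traces and feature tables, JSON for configs, models, and reports:
everything human-diffable. An HR CSV has header ``time_s,hr_bpm``; session
metadata (subject id, label) lives in an optional JSON sidecar next to it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .hr_features import (
    FeatureVector,
    HRSeries,
    SessionLabel,
    WindowSpec,
    extract_features,
)
from .indicator import IndicatorConfig, track_session
from .perceptron import MLPConfig, MLPModel, evaluate, train
from .synthetic import ClassProfile, generate_cohort, idh_profile, normal_profile

__all__ = [
    "read_hr_csv",
    "write_hr_csv",
    "read_features_csv",
    "write_features_csv",
    "RunConfig",
    "run_end_to_end",
]

log = logging.getLogger("dialysentinel")


def read_hr_csv(path: str | Path) -> HRSeries:
    """Read and validate an HR trace; errors name the offending file row."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "hr_bpm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    hr = df["hr_bpm"].to_numpy(dtype=float)

    def row(i: int) -> int:  # 1-based file row, counting the header line
        return i + 2

    if t.size >= 2:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(f"{path}: time_s not strictly increasing at row {row(int(bad[0]) + 1)}")
    bad = np.flatnonzero(~np.isfinite(hr) | (hr <= 20) | (hr >= 250))
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"{path}: hr_bpm value {hr[i]} out of range (20, 250) at row {row(i)}")

    subject_id, label = "", None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        subject_id = meta.get("subject_id", "")
        label = SessionLabel(meta["label"]) if meta.get("label") else None
    return HRSeries(time_s=t, hr_bpm=hr, label=label, subject_id=subject_id)


def write_hr_csv(series: HRSeries, path: str | Path, sidecar: bool = True) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": series.time_s, "hr_bpm": series.hr_bpm}).to_csv(path, index=False)
    if sidecar and (series.subject_id or series.label is not None):
        meta = {
            "subject_id": series.subject_id,
            "label": series.label.value if series.label else None,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def write_features_csv(
    features: list[FeatureVector], path: str | Path, spec: WindowSpec | None = None
) -> Path:
    spec = spec or WindowSpec()
    names = [f"{side}_{L}" for L in spec.lengths_s for side in ("upper", "lower")]
    rows = []
    for fv in features:
        if len(fv) != len(names):
            raise ValueError(f"feature vector length {len(fv)} does not match spec ({len(names)})")
        rows.append(
            {"subject_id": fv.subject_id, "label": fv.label.value if fv.label else ""}
            | dict(zip(names, fv.values))
        )
    path = Path(path)
    pd.DataFrame(rows, columns=["subject_id", "label", *names]).to_csv(path, index=False)
    return path


def read_features_csv(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(path, keep_default_na=False)
    value_cols = [c for c in df.columns if c.startswith(("upper_", "lower_"))]
    if not value_cols:
        raise ValueError(f"{path}: no feature columns (upper_*/lower_*) found")
    out = []
    for _, r in df.iterrows():
        out.append(
            FeatureVector(
                values=r[value_cols].to_numpy(dtype=float),
                label=SessionLabel(r["label"]) if r.get("label") else None,
                subject_id=str(r.get("subject_id", "")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# run configuration


_RUNCONFIG_KEYS = {
    "n_normal", "n_idh", "seed", "out_dir",
    "window", "indicator", "mlp", "profiles",
}


def _windowspec_to_dict(w: WindowSpec) -> dict:
    return {"start_index": w.start_index, "lengths_s": list(w.lengths_s)}


def _profile_to_dict(p: ClassProfile) -> dict:
    return {
        "label": p.label.value,
        "area_targets_upper": list(p.area_targets_upper),
        "area_targets_lower": list(p.area_targets_lower),
        "dispersion": p.dispersion,
        "baseline_hr_range": list(p.baseline_hr_range),
        "noise_sd": p.noise_sd,
    }


def _profile_from_dict(d: dict) -> ClassProfile:
    return ClassProfile(
        label=SessionLabel(d["label"]),
        area_targets_upper=tuple(d["area_targets_upper"]),
        area_targets_lower=tuple(d["area_targets_lower"]),
        dispersion=d["dispersion"],
        baseline_hr_range=tuple(d["baseline_hr_range"]),
        noise_sd=d["noise_sd"],
    )


@dataclasses.dataclass
class RunConfig:
    """One JSON-serializable document driving the whole pipeline."""

    n_normal: int = 53
    n_idh: int = 42
    seed: int = 0
    out_dir: str = "out"
    window: WindowSpec = dataclasses.field(default_factory=WindowSpec)
    indicator: IndicatorConfig = dataclasses.field(default_factory=IndicatorConfig)
    mlp: MLPConfig = dataclasses.field(default_factory=MLPConfig)
    profiles: tuple[ClassProfile, ClassProfile] = dataclasses.field(
        default_factory=lambda: (normal_profile(), idh_profile())
    )

    def to_dict(self) -> dict:
        m = self.mlp
        return {
            "n_normal": self.n_normal,
            "n_idh": self.n_idh,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "window": _windowspec_to_dict(self.window),
            "indicator": {"saturation": self.indicator.saturation, "tiers": list(self.indicator.tiers)},
            "mlp": {
                "n_hidden_layers": m.n_hidden_layers,
                "hidden_width": m.hidden_width,
                "n_outputs": m.n_outputs,
                "max_epochs": m.max_epochs,
                "split": list(m.split),
                "seed": m.seed,
                "early_stopping": m.early_stopping,
                "patience": m.patience,
            },
            "profiles": [_profile_to_dict(p) for p in self.profiles],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        kw: dict = {}
        for key in ("n_normal", "n_idh", "seed", "out_dir"):
            if key in d:
                kw[key] = d[key]
        if "window" in d:
            kw["window"] = WindowSpec(
                start_index=d["window"]["start_index"],
                lengths_s=tuple(d["window"]["lengths_s"]),
            )
        if "indicator" in d:
            kw["indicator"] = IndicatorConfig(
                saturation=d["indicator"]["saturation"], tiers=tuple(d["indicator"]["tiers"])
            )
        if "mlp" in d:
            m = d["mlp"]
            kw["mlp"] = MLPConfig(
                n_hidden_layers=m["n_hidden_layers"],
                hidden_width=m["hidden_width"],
                n_outputs=m["n_outputs"],
                max_epochs=m["max_epochs"],
                split=tuple(m["split"]),
                seed=m["seed"],
                early_stopping=m["early_stopping"],
                patience=m["patience"],
            )
        if "profiles" in d:
            kw["profiles"] = tuple(_profile_from_dict(p) for p in d["profiles"])
        return cls(**kw)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _dump_json(obj, path: Path) -> Path:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))
    return path


def run_end_to_end(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """simulate -> extract -> indicate -> train -> evaluate, seed-deterministic.

    Writes features.csv, indicators.jsonl, model.json, and report.json under
    out_dir and returns their paths plus the in-memory reports.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    cases = generate_cohort(config.n_normal, config.n_idh, config.profiles, config.seed)
    log.info("simulate: %d cases (%.1f s)", len(cases), time.perf_counter() - t0)

    t0 = time.perf_counter()
    features = [extract_features(c.series, config.window)[0] for c in cases]
    feats_path = write_features_csv(features, out / "features.csv", config.window)
    log.info("extract: %d x %d features (%.1f s)", len(features),
             2 * config.window.count, time.perf_counter() - t0)

    t0 = time.perf_counter()
    with (out / "indicators.jsonl").open("w") as fh:
        for case in cases:
            states = track_session(case.series, config.window, config.indicator)
            fh.write(json.dumps({
                "subject_id": case.series.subject_id,
                "label": case.label.value,
                "states": [
                    {"window_length_s": s.window_length_s, "low_pct": s.low_pct,
                     "high_pct": s.high_pct, "tier": s.tier.value}
                    for s in states
                ],
            }, sort_keys=True) + "\n")
    log.info("indicate: %d sessions (%.1f s)", len(cases), time.perf_counter() - t0)

    t0 = time.perf_counter()
    mlp_cfg = dataclasses.replace(config.mlp, seed=config.seed)
    model = train(features, mlp_cfg)
    model_path = _dump_json(model.to_dict(), out / "model.json")
    log.info("train: %d-layer MLP on %d cases (%.1f s)",
             mlp_cfg.n_hidden_layers, len(model.train_idx), time.perf_counter() - t0)

    reports = {}
    for name, idx in (("train", model.train_idx), ("val", model.val_idx), ("test", model.test_idx)):
        subset = [features[i] for i in idx]
        reports[name] = evaluate(model, subset).to_dict() if subset else None
    report_path = _dump_json(reports, out / "report.json")
    test_acc = reports["test"]["acc"] if reports["test"] else float("nan")
    log.info("evaluate: test ACC %.1f%%", test_acc)

    return {
        "features_csv": feats_path,
        "indicators_jsonl": out / "indicators.jsonl",
        "model_json": model_path,
        "report_json": report_path,
        "reports": reports,
        "model": model,
        "cases": cases,
    }
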