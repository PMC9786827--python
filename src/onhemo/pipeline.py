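"""End-to-end orchestration: quality gate -> segmentation -> colourimetry ->
indices, plus model building (normative DB, classifier, calibrations) and
per-eye reporting.  Every output carries the config hash and seed."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, hb_colorimetry, quality_gate, segmentation
from .config import PipelineConfig
from .indices import (
    SECTOR_COLUMNS,
    ClassifierStandin,
    IndexCalibration,
    NormativeDB,
    build_normative_db,
    calibrate_index,
    compute_gdf,
    compute_gip,
    DiscriminantWeights,
    featureize,
    measurement_frame,
    raw_discriminant,
    train_classifier_standin,
)
from .synthetic_fundus import make_eye_profile, simulate_measurements

__all__ = ["ModelBundle", "build_models", "analyze_image", "run_analyze",
           "run_report", "write_table", "read_table"]


@dataclass
class ModelBundle:
    """Everything needed to score an eye: normative DB, classifier stand-in,
    and the GDF/GIP calibrations, tied to a config hash and seed."""

    db: NormativeDB
    classifier: ClassifierStandin
    cal_gdf: IndexCalibration
    cal_gip: IndexCalibration
    config_hash: str
    seed: int

    def save(self, path: str | Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "db": json.loads(_db_json(self.db)),
            "classifier": self.classifier.to_dict(),
            "cal_gdf": self.cal_gdf.to_dict(),
            "cal_gip": self.cal_gip.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        d = json.loads(Path(path).read_text())
        db = NormativeDB(
            tertile_edges=np.array(d["db"]["tertile_edges"]),
            sector_refs=[[np.array(a) for a in s] for s in d["db"]["sector_refs"]],
            vcd_refs=[np.array(a) for a in d["db"]["vcd_refs"]],
            cup_refs=[np.array(a) for a in d["db"]["cup_refs"]],
            n_reference=d["db"]["n_reference"],
            provenance=d["db"].get("provenance", {}),
        )
        return cls(db=db,
                   classifier=ClassifierStandin.from_dict(d["classifier"]),
                   cal_gdf=IndexCalibration.from_dict(d["cal_gdf"]),
                   cal_gip=IndexCalibration.from_dict(d["cal_gip"]),
                   config_hash=d["config_hash"], seed=d["seed"])


def _db_json(db: NormativeDB) -> str:
    return json.dumps({
        "tertile_edges": db.tertile_edges.tolist(),
        "sector_refs": [[a.tolist() for a in s] for s in db.sector_refs],
        "vcd_refs": [a.tolist() for a in db.vcd_refs],
        "cup_refs": [a.tolist() for a in db.cup_refs],
        "n_reference": db.n_reference,
        "provenance": db.provenance,
    })


def simulate_feature_cohort(
    n_eyes: int,
    cfg: PipelineConfig,
    seed: int,
    severity: float | tuple[float, float] = 0.0,
) -> pd.DataFrame:
    """Feature-level simulated cohort (no rasterisation).

    ``severity`` is either a fixed value or a (lo, hi) uniform range drawn
    per eye.  Returns one row per eye with the measured features plus the
    true severity column.
    """
    rng = np.random.default_rng(seed)
    measurements, sev = [], []
    for _ in range(n_eyes):
        g = (rng.uniform(*severity) if isinstance(severity, tuple)
             else float(severity))
        gt = make_eye_profile(cfg.generator, severity=g, seed=rng)
        measurements.append(simulate_measurements(gt, cfg.generator, rng))
        sev.append(g)
    frame = measurement_frame(measurements)
    frame["severity"] = sev
    return frame


def build_models(
    cfg: PipelineConfig,
    n_normals: int = 2000,
    n_glaucoma: int = 800,
    seed: int = 0,
) -> ModelBundle:
    """Build DB + classifier + calibrations from a simulated normal cohort.

    The normative DB and the calibration anchors are built from severity-0
    eyes only; the classifier stand-in additionally sees a glaucoma cohort
    with severities drawn uniformly from [0.3, 1].

    The classifier scores entering the calibration are cross-fitted (each
    normal eye is scored by a model trained without its fold), so the anchor
    quantiles reflect the out-of-sample score distribution and the intended
    5%/1% rates transfer to fresh eyes without optimism bias.
    """
    ss = np.random.SeedSequence(seed)
    s_norm, s_glau = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    normals = simulate_feature_cohort(n_normals, cfg, s_norm, severity=0.0)
    glaucoma = simulate_feature_cohort(n_glaucoma, cfg, s_glau, severity=(0.3, 1.0))

    db = build_normative_db(normals, cfg.indices,
                            provenance={"seed": seed, "n": n_normals,
                                        "config_hash": cfg.config_hash})

    def _featurize_frame(frame: pd.DataFrame) -> list:
        fvs = []
        for _, row in frame.iterrows():
            measured = {
                "sector_hb": row[SECTOR_COLUMNS].to_numpy(dtype=float),
                "vertical_cd": float(row["vertical_cd"]),
                "cup_area_pct": float(row["cup_area_pct"]),
                "disc_area": float(row["disc_area"]),
            }
            fvs.append(featureize(measured, db))
        return fvs

    fv_norm = _featurize_frame(normals)
    fv_glau = _featurize_frame(glaucoma)
    X_norm = np.array([fv.as_array() for fv in fv_norm])
    X_glau = np.array([fv.as_array() for fv in fv_glau])
    X = np.vstack([X_norm, X_glau])
    y = np.r_[np.ones(len(fv_norm)), np.zeros(len(fv_glau))]
    classifier = train_classifier_standin(X, y)

    # cross-fitted scores for the held-in normals (5 deterministic folds)
    scores = np.empty(len(fv_norm))
    folds = np.arange(len(fv_norm)) % 5
    for k in range(5):
        train_idx = folds != k
        clf_k = train_classifier_standin(
            np.vstack([X_norm[train_idx], X_glau]),
            np.r_[np.ones(int(train_idx.sum())), np.zeros(len(fv_glau))])
        scores[folds == k] = clf_k.score_many(X_norm[folds == k])
    for fv, s in zip(fv_norm, scores):
        fv.classifier_score = float(s)

    w_gdf = DiscriminantWeights.gdf(cfg.indices)
    w_gip = DiscriminantWeights.gip(cfg.indices)
    raw_gdf = np.array([raw_discriminant(fv, w_gdf, True) for fv in fv_norm])
    raw_gip = np.array([raw_discriminant(fv, w_gip, False) for fv in fv_norm])
    cal_gdf = calibrate_index(raw_gdf, cfg.indices, uses_classifier=True)
    cal_gip = calibrate_index(raw_gip, cfg.indices, uses_classifier=False)
    return ModelBundle(db=db, classifier=classifier, cal_gdf=cal_gdf,
                       cal_gip=cal_gip, config_hash=cfg.config_hash, seed=seed)


def score_frame(frame: pd.DataFrame, bundle: ModelBundle,
                cfg: PipelineConfig) -> pd.DataFrame:
    """GDF/GIP for every row of a measured-feature table."""
    out = []
    for _, row in frame.iterrows():
        measured = {
            "sector_hb": row[SECTOR_COLUMNS].to_numpy(dtype=float),
            "vertical_cd": float(row["vertical_cd"]),
            "cup_area_pct": float(row["cup_area_pct"]),
            "disc_area": float(row["disc_area"]),
        }
        s = score_measurements(measured, bundle, cfg)
        out.append({"GDF": s["GDF"], "GIP": s["GIP"],
                    "classifier_score": s["classifier_score"]})
    res = pd.DataFrame(out, index=frame.index)
    keep = [c for c in ("severity", "disc_area", "vertical_cd", "cup_area_pct")
            if c in frame.columns]
    return pd.concat([frame[keep], res], axis=1)


def score_measurements(measured: dict, bundle: ModelBundle,
                       cfg: PipelineConfig) -> dict:
    """GDF/GIP (and the feature vector) for one eye's measurements."""
    fv = featureize(measured, bundle.db, bundle.classifier)
    return {
        "GDF": compute_gdf(fv, bundle.cal_gdf, cfg.indices),
        "GIP": compute_gip(fv, bundle.cal_gip, cfg.indices),
        "classifier_score": fv.classifier_score,
        "feature_vector": fv,
    }


def analyze_image(image: np.ndarray, eye: str, scale: float,
                  cfg: PipelineConfig, bundle: ModelBundle
                  ) -> tuple[dict | None, quality_gate.QualityReport]:
    """Full single-image analysis; returns (row, quality report).

    ``row`` is None when the image is excluded; a vessel-reference failure
    downgrades the image to the low_quality category.
    """
    canonical = segmentation.mirror_normalize(image, eye)
    seg = segmentation.detect_disc(canonical, scale, cfg.segmentation)
    report = quality_gate.assess_quality(canonical, seg, cfg.quality)
    if not report.analysable:
        return None, report
    vessels = segmentation.segment_vessels(canonical, seg, cfg.segmentation)
    try:
        ref = hb_colorimetry.vessel_reference(canonical, vessels, cfg.colorimetry)
    except hb_colorimetry.ReferenceError:
        report = quality_gate.QualityReport(False, "low_quality", report.metrics)
        return None, report
    hb = hb_colorimetry.hb_map(canonical, seg.disc_mask, vessels, ref,
                               cfg.colorimetry)
    profile = hb_colorimetry.sector_profile(hb, seg)
    cup = hb_colorimetry.estimate_cup(hb, seg, scale, cfg.colorimetry)
    measured = {
        "sector_hb": profile.values,
        "vertical_cd": cup.vertical_cd,
        "cup_area_pct": cup.cup_area_pct,
        "disc_area": seg.disc_area,
    }
    scored = score_measurements(measured, bundle, cfg)
    row = {
        "disc_area": seg.disc_area,
        "cup_area_pct": cup.cup_area_pct,
        "vertical_cd": cup.vertical_cd,
        "vessel_reference": ref,
        "GDF": scored["GDF"],
        "GIP": scored["GIP"],
        "classifier_score": scored["classifier_score"],
    }
    row.update({SECTOR_COLUMNS[i]: profile.values[i]
                for i in range(geometry.N_SECTORS)})
    return row, report


def run_analyze(metadata: pd.DataFrame, images_dir: str | Path,
                cfg: PipelineConfig, bundle: ModelBundle,
                out_csv: str | Path | None = None,
                log=lambda msg: None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyse an image set described by a metadata table.

    ``metadata`` needs columns patient_id, eye, exam_date, image_path,
    scale_mm_per_px.  Returns (results, exclusions); both are written to
    disk when ``out_csv`` is given.  Deterministic given inputs + config.
    """
    from PIL import Image

    if bundle.config_hash != cfg.config_hash:
        raise ValueError("model bundle was built with a different config "
                         f"({bundle.config_hash} != {cfg.config_hash})")
    images_dir = Path(images_dir)
    rows, exclusions = [], []
    for _, meta in metadata.iterrows():
        img = np.asarray(Image.open(images_dir / meta["image_path"]).convert("RGB"))
        row, report = analyze_image(img, meta["eye"],
                                    float(meta["scale_mm_per_px"]), cfg, bundle)
        base = {k: meta[k] for k in ("patient_id", "eye", "exam_date", "image_path")
                if k in meta}
        if row is None:
            exclusions.append({**base, "category": report.category,
                               **report.metrics})
            log(f"{meta['image_path']}: excluded ({report.category})")
        else:
            rows.append({**base, **row})
            log(f"{meta['image_path']}: ok GDF={row['GDF']:.1f} GIP={row['GIP']:.1f}")
    results = pd.DataFrame(rows)
    excl = pd.DataFrame(exclusions)
    if out_csv is not None:
        write_table(results, out_csv, cfg.config_hash, bundle.seed)
        write_table(excl, Path(out_csv).with_suffix(".exclusions.csv"),
                    cfg.config_hash, bundle.seed)
    return results, excl


def run_report(results: pd.DataFrame, eye_id: str | None = None) -> str:
    """Human-readable per-eye summary: index values and sector flags.

    Sectors whose Hb percentile falls below the normative median are listed;
    regenerating the report from the same table is byte-identical.
    """
    lines = []
    key = results.apply(lambda r: f"{r['patient_id']}:{r['eye']}", axis=1)
    results = results.assign(_key=key)
    if eye_id is not None:
        if eye_id not in set(key):
            raise KeyError(f"unknown eye id {eye_id!r}")
        results = results[results["_key"] == eye_id]
    for k, sub in results.groupby("_key", sort=True):
        last = sub.sort_values("exam_date").iloc[-1] if "exam_date" in sub else sub.iloc[-1]
        lines.append(f"eye {k}")
        lines.append(f"  GDF {last['GDF']:+.1f}   GIP {last['GIP']:+.1f}   "
                     f"disc {last['disc_area']:.2f} mm^2   "
                     f"vertical C/D {last['vertical_cd']:.2f}")
        if "sector_pct_below_median" in last:
            lines.append(f"  sectors below normative median: "
                         f"{last['sector_pct_below_median']}")
        if "prog_slope" in last and np.isfinite(last.get("prog_slope", np.nan)):
            lines.append(f"  progression: slope {last['prog_slope']:+.2f}/yr "
                         f"(p={last['prog_p']:.4f}, "
                         f"{'flagged' if last.get('prog_flagged') else 'not flagged'})")
        lines.append("")
    return "\n".join(lines)


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str,
                seed: int | None = None) -> None:
    """CSV with a provenance comment line (config hash, seed)."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
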