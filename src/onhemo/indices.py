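"""Normative percentile database and the calibrated GDF / GIP indices.

GDF (glaucoma discriminant function) combines the percentiles of the 24
sector haemoglobin values relative to a disease-free reference population,
the vertical cup/disc ratio, and a near-dichotomous normal-vs-glaucoma
classifier score, into a single value calibrated on the normal population:
0 is (approximately) the value exceeded by 95% of normal eyes and -15 the
value exceeded by 99%.  Lower values are more glaucomatous; the working
range is clipped to [-100, +85].

GIP (globin individual pointer) is the same construction with no weight on
the classifier, trading diagnostic power for reproducibility — the index of
choice for progression analysis — with range [-100, +100].

Disc-area weighting is implemented by stratifying the percentile lookup by
disc-area tertile of the reference population, which makes the indices
independent of disc size by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import geometry
from .config import IndexConfig

__all__ = [
    "NormativeDB",
    "FeatureVector",
    "IndexCalibration",
    "DiscriminantWeights",
    "build_normative_db",
    "empirical_percentile",
    "ClassifierStandin",
    "train_classifier_standin",
    "featureize",
    "raw_discriminant",
    "calibrate_index",
    "compute_gdf",
    "compute_gip",
    "measurement_frame",
]

SECTOR_COLUMNS = [f"sector_{i:02d}" for i in range(geometry.N_SECTORS)]


def empirical_percentile(sorted_ref: np.ndarray, x: float) -> float:
    """Midpoint-tie empirical percentile: 100*(#below + 0.5*#equal)/n."""
    n = sorted_ref.size
    lo = int(np.searchsorted(sorted_ref, x, side="left"))
    hi = int(np.searchsorted(sorted_ref, x, side="right"))
    return 100.0 * (lo + 0.5 * (hi - lo)) / n


def _percentile_vec(sorted_ref: np.ndarray, x: np.ndarray) -> np.ndarray:
    lo = np.searchsorted(sorted_ref, x, side="left")
    hi = np.searchsorted(sorted_ref, x, side="right")
    return 100.0 * (lo + 0.5 * (hi - lo)) / sorted_ref.size


@dataclass
class NormativeDB:
    """Per-feature empirical percentile curves from severity-0 reference eyes,
    stratified by disc-area tertile."""

    tertile_edges: np.ndarray  # (n_strata - 1,) disc-area break points, mm^2
    sector_refs: list  # [stratum][sector] -> sorted np.ndarray
    vcd_refs: list  # [stratum] -> sorted np.ndarray
    cup_refs: list  # [stratum] -> sorted np.ndarray
    n_reference: int
    provenance: dict = field(default_factory=dict)

    def stratum(self, disc_area: float) -> int:
        return int(np.searchsorted(self.tertile_edges, disc_area))

    def sector_percentiles(self, sector_hb: np.ndarray, disc_area: float) -> np.ndarray:
        s = self.stratum(disc_area)
        return np.array([
            empirical_percentile(self.sector_refs[s][i], sector_hb[i])
            for i in range(geometry.N_SECTORS)
        ])

    def vcd_percentile(self, vcd: float, disc_area: float) -> float:
        return empirical_percentile(self.vcd_refs[self.stratum(disc_area)], vcd)

    def cup_percentile(self, cup_area_pct: float, disc_area: float) -> float:
        return empirical_percentile(self.cup_refs[self.stratum(disc_area)], cup_area_pct)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tertile_edges": self.tertile_edges.tolist(),
            "sector_refs": [[a.tolist() for a in s] for s in self.sector_refs],
            "vcd_refs": [a.tolist() for a in self.vcd_refs],
            "cup_refs": [a.tolist() for a in self.cup_refs],
            "n_reference": self.n_reference,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeDB":
        d = json.loads(Path(path).read_text())
        return cls(
            tertile_edges=np.array(d["tertile_edges"]),
            sector_refs=[[np.array(a) for a in s] for s in d["sector_refs"]],
            vcd_refs=[np.array(a) for a in d["vcd_refs"]],
            cup_refs=[np.array(a) for a in d["cup_refs"]],
            n_reference=d["n_reference"],
            provenance=d.get("provenance", {}),
        )


@dataclass
class FeatureVector:
    sector_percentiles: np.ndarray  # (24,) in [0, 100]
    vertical_cd: float
    vcd_percentile: float
    cup_area_pct: float
    cup_percentile: float
    disc_area: float
    classifier_score: float = 1.0

    def __post_init__(self):
        self.sector_percentiles = np.asarray(self.sector_percentiles, dtype=float)
        vals = np.r_[self.sector_percentiles, self.vertical_cd, self.vcd_percentile,
                     self.cup_area_pct, self.disc_area, self.classifier_score]
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature vector contains non-finite values")
        if (self.sector_percentiles.min() < 0) or (self.sector_percentiles.max() > 100):
            raise ValueError("sector percentiles outside [0, 100]")

    def as_array(self) -> np.ndarray:
        """Flat numeric form used by the classifier stand-in."""
        return np.r_[self.sector_percentiles, self.vertical_cd,
                     self.cup_area_pct, self.disc_area]


@dataclass
class IndexCalibration:
    """Affine map raw -> index anchored on the normal population."""

    a: float
    b: float
    clip: tuple[float, float]
    uses_classifier: bool
    anchors: dict = field(default_factory=dict)

    def apply(self, raw: float) -> float:
        return float(np.clip(self.a * raw + self.b, *self.clip))

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "clip": list(self.clip),
                "uses_classifier": self.uses_classifier, "anchors": self.anchors}

    @classmethod
    def from_dict(cls, d: dict) -> "IndexCalibration":
        return cls(a=d["a"], b=d["b"], clip=tuple(d["clip"]),
                   uses_classifier=d["uses_classifier"], anchors=d.get("anchors", {}))


@dataclass
class DiscriminantWeights:
    w_sector: float
    w_cd: float
    w_classifier: float
    supinf_multiplier: float = 2.0

    @classmethod
    def gdf(cls, cfg: IndexConfig) -> "DiscriminantWeights":
        return cls(cfg.gdf_weight_sector, cfg.gdf_weight_cd,
                   cfg.gdf_weight_classifier, cfg.supinf_multiplier)

    @classmethod
    def gip(cls, cfg: IndexConfig) -> "DiscriminantWeights":
        return cls(cfg.gip_weight_sector, cfg.gip_weight_cd, 0.0,
                   cfg.supinf_multiplier)

    def sector_weight_vector(self) -> np.ndarray:
        w = np.ones(geometry.N_SECTORS)
        w[geometry.supinf_sector_mask()] = self.supinf_multiplier
        return w


def measurement_frame(measurements: list[dict]) -> pd.DataFrame:
    """Tabulate `simulate_measurements`-style dicts (one row per eye)."""
    rows = []
    for m in measurements:
        row = {SECTOR_COLUMNS[i]: m["sector_hb"][i] for i in range(geometry.N_SECTORS)}
        row.update(vertical_cd=m["vertical_cd"], cup_area_pct=m["cup_area_pct"],
                   disc_area=m["disc_area"])
        rows.append(row)
    return pd.DataFrame(rows)


def build_normative_db(reference: pd.DataFrame, cfg: IndexConfig | None = None,
                       provenance: dict | None = None) -> NormativeDB:
    """Empirical percentile curves from a disease-free reference table.

    ``reference`` must contain the 24 ``sector_XX`` columns plus
    ``vertical_cd``, ``cup_area_pct`` and ``disc_area``; it must hold only
    severity-0 eyes (caller's contract).
    """
    cfg = cfg or IndexConfig()
    n = len(reference)
    if n < cfg.min_reference_eyes:
        raise ValueError(f"need >= {cfg.min_reference_eyes} reference eyes, got {n}")
    qs = np.linspace(0, 100, cfg.n_disc_area_strata + 1)[1:-1]
    edges = np.percentile(reference["disc_area"], qs)
    strata = np.searchsorted(edges, reference["disc_area"].to_numpy())

    sector_refs, vcd_refs, cup_refs = [], [], []
    for s in range(cfg.n_disc_area_strata):
        sub = reference[strata == s]
        sector_refs.append([np.sort(sub[c].to_numpy()) for c in SECTOR_COLUMNS])
        vcd_refs.append(np.sort(sub["vertical_cd"].to_numpy()))
        cup_refs.append(np.sort(sub["cup_area_pct"].to_numpy()))
    return NormativeDB(tertile_edges=np.asarray(edges), sector_refs=sector_refs,
                       vcd_refs=vcd_refs, cup_refs=cup_refs, n_reference=n,
                       provenance=provenance or {})


class ClassifierStandin:
    """Trainable normal-vs-glaucoma discriminator on the feature vector.

    A logistic model on the (disc-area adjusted) features; its score is the
    probability of the *normal* class, so values accumulate near 1 for
    normal eyes and near 0 for glaucomatous ones.  Inference is
    deterministic: identical input, identical score.
    """

    def __init__(self):
        self._model = LogisticRegression(max_iter=2000)
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    def fit(self, X: np.ndarray, y_normal: np.ndarray) -> "ClassifierStandin":
        y = np.asarray(y_normal, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("need both normal and glaucoma examples")
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self._model.fit((X - self._mu) / self._sd, y)
        return self

    def score(self, features: "FeatureVector | np.ndarray") -> float:
        x = features.as_array() if isinstance(features, FeatureVector) else np.asarray(features)
        z = (x - self._mu) / self._sd
        normal_col = int(np.flatnonzero(self._model.classes_ == 1)[0])
        return float(self._model.predict_proba(z[None, :])[0, normal_col])

    def score_many(self, X: np.ndarray) -> np.ndarray:
        z = (X - self._mu) / self._sd
        normal_col = int(np.flatnonzero(self._model.classes_ == 1)[0])
        return self._model.predict_proba(z)[:, normal_col]

    def to_dict(self) -> dict:
        return {"coef": self._model.coef_.tolist(),
                "intercept": self._model.intercept_.tolist(),
                "classes": self._model.classes_.tolist(),
                "mu": self._mu.tolist(), "sd": self._sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierStandin":
        obj = cls()
        obj._model.coef_ = np.array(d["coef"])
        obj._model.intercept_ = np.array(d["intercept"])
        obj._model.classes_ = np.array(d["classes"])
        obj._mu = np.array(d["mu"])
        obj._sd = np.array(d["sd"])
        return obj


def train_classifier_standin(features: np.ndarray, labels_normal: np.ndarray
                             ) -> ClassifierStandin:
    """Fit the stand-in on a labelled feature table (1 = normal, 0 = glaucoma)."""
    return ClassifierStandin().fit(np.asarray(features, dtype=float),
                                   np.asarray(labels_normal))


def featureize(measured: dict, db: NormativeDB,
               classifier: ClassifierStandin | None = None) -> FeatureVector:
    """Percentile-transform one eye's measurements against the normative DB."""
    sector_pct = db.sector_percentiles(measured["sector_hb"], measured["disc_area"])
    vcd_pct = db.vcd_percentile(measured["vertical_cd"], measured["disc_area"])
    cup_pct = db.cup_percentile(measured["cup_area_pct"], measured["disc_area"])
    fv = FeatureVector(
        sector_percentiles=sector_pct,
        vertical_cd=measured["vertical_cd"],
        vcd_percentile=vcd_pct,
        cup_area_pct=measured["cup_area_pct"],
        cup_percentile=cup_pct,
        disc_area=measured["disc_area"],
    )
    if classifier is not None:
        fv.classifier_score = classifier.score(fv)
    return fv


def raw_discriminant(fv: FeatureVector, weights: DiscriminantWeights,
                     use_classifier: bool) -> float:
    """Weighted sum of deficit terms; higher = more normal.

    * sector term: weighted mean of (percentile - 50)/50, superior/inferior
      wedges double-weighted;
    * C/D term: (50 - vcd_percentile)/50 (large cups are abnormal);
    * classifier term (iff enabled): w_cls * (score - 1), zero for a fully
      normal score — the documented neutral raw value is therefore 0.
    """
    w = weights.sector_weight_vector()
    sector_term = float(np.sum(w * (fv.sector_percentiles - 50.0) / 50.0) / w.sum())
    cd_term = (50.0 - fv.vcd_percentile) / 50.0
    raw = weights.w_sector * sector_term + weights.w_cd * cd_term
    if use_classifier:
        raw += weights.w_classifier * (fv.classifier_score - 1.0)
    return float(raw)


def calibrate_index(raw_scores: np.ndarray, cfg: IndexConfig | None = None,
                    uses_classifier: bool = True) -> IndexCalibration:
    """Anchor the affine map on held-in normal raw scores.

    Solves a*q05 + b = 0 and a*q01 + b = -15 (defaults), where q05/q01 are
    the empirical 5th/1st percentiles of the normal raw-score distribution;
    requires a positive spread between the anchors.
    """
    cfg = cfg or IndexConfig()
    raw_scores = np.asarray(raw_scores, dtype=float)
    if raw_scores.size < cfg.min_reference_eyes:
        raise ValueError(f"need >= {cfg.min_reference_eyes} normal raw scores")
    q_hi = float(np.percentile(raw_scores, cfg.anchor_upper_pct))
    q_lo = float(np.percentile(raw_scores, cfg.anchor_lower_pct))
    if q_hi <= q_lo:
        raise ValueError("degenerate spread between anchor quantiles")
    a = (cfg.anchor_upper_value - cfg.anchor_lower_value) / (q_hi - q_lo)
    b = cfg.anchor_upper_value - a * q_hi
    clip = cfg.gdf_clip if uses_classifier else cfg.gip_clip
    return IndexCalibration(
        a=float(a), b=float(b), clip=tuple(clip), uses_classifier=uses_classifier,
        anchors={"q_upper_raw": q_hi, "q_lower_raw": q_lo,
                 "upper": [cfg.anchor_upper_pct, cfg.anchor_upper_value],
                 "lower": [cfg.anchor_lower_pct, cfg.anchor_lower_value]},
    )


def compute_gdf(fv: FeatureVector, calibration: IndexCalibration,
                cfg: IndexConfig | None = None) -> float:
    """Calibrated, clipped GDF; lower = more glaucomatous."""
    cfg = cfg or IndexConfig()
    if not calibration.uses_classifier:
        raise ValueError("GDF requires a calibration built with the classifier term")
    raw = raw_discriminant(fv, DiscriminantWeights.gdf(cfg), use_classifier=True)
    return calibration.apply(raw)


def compute_gip(fv: FeatureVector, calibration: IndexCalibration,
                cfg: IndexConfig | None = None) -> float:
    """Calibrated, clipped GIP: no classifier term, more reproducible."""
    cfg = cfg or IndexConfig()
    if calibration.uses_classifier:
        raise ValueError("GIP requires a classifier-free calibration")
    raw = raw_discriminant(fv, DiscriminantWeights.gip(cfg), use_classifier=False)
    return calibration.apply(raw)
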