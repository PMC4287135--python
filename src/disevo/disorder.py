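"""Per-residue flexibility profiles and whole-sequence CH-CDF classification.

Per-residue scores come from a fold-index (charge-hydropathy) stand-in
predictor: over a centered window (shrunk symmetrically at the termini) the
fold index is

    F = 2.785 * <H> - |<R>| - 1.151

with <H> the mean Kyte-Doolittle hydropathy normalized to [0, 1] via
(v + 4.5) / 9 and <R> the mean net charge per residue (K, R = +1; D, E = -1;
H and everything else neutral; 'X' is neutral with hydropathy 0.5). The
disorder score is ``clamp(0.5 - F, 0, 1)``; residues above 0.5 are called
disordered. The same boundary line R = 2.785*H - 1.151 defines the
charge-hydropathy (CH) plot distance dCH = R - (2.785*H - 1.151) on
whole-sequence composition, and the cumulative distribution of per-residue
scores against a calibrated 7-point boundary defines dCDF. The sign pair
(dCH, dCDF) splits proteins into quadrants Q1-Q4: Q2 (dCH < 0, dCDF >= 0) is
structure-prone, Q3 and Q4 (dCDF < 0) are disorder-prone, Q1 carries excess
charge but may be structured.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .records import AA20, DomainAnnotation, ProteinRecord

#: Name under which the stand-in predictor is reported in outputs/manifests.
PREDICTOR_NAME = "fold-index (charge-hydropathy) stand-in"

# Fold-index / CH-boundary line coefficients (R_b = CH_SLOPE * H - CH_OFFSET).
CH_SLOPE = 2.785
CH_OFFSET = 1.151

#: Kyte-Doolittle hydropathy, raw scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

#: Default smoothing window (residues) for per-residue profiles.
DEFAULT_WINDOW = 51

#: Default CDF evaluation thresholds.
DEFAULT_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)


def normalized_hydropathy(residue: str) -> float:
    """Kyte-Doolittle hydropathy mapped to [0, 1]; 'X' is neutral (0.5)."""
    if residue == "X":
        return 0.5
    try:
        return (KYTE_DOOLITTLE[residue] + 4.5) / 9.0
    except KeyError:
        raise ValidationError(f"unknown residue {residue!r}") from None


def residue_charge(residue: str) -> float:
    return _CHARGE.get(residue, 0.0)


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue flexibility scores in [0, 1] for one protein."""

    protein_id: str
    scores: np.ndarray
    window: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValidationError("profile must be a non-empty 1-D score vector")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValidationError("profile scores must lie in [0, 1]")

    def __len__(self) -> int:
        return self.scores.size

    @property
    def fraction_disordered(self) -> float:
        """Fraction of residues with score > 0.5."""
        return float(np.mean(self.scores > 0.5))


@dataclass(frozen=True)
class CdfBoundary:
    """Order/disorder boundary for the CDF plot: 7 thresholds, 7 values."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, float)
        v = np.asarray(self.values, float)
        if t.size != 7 or v.size != 7:
            raise ParameterError("CDF boundary needs exactly 7 thresholds and 7 values")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("CDF thresholds must be strictly increasing")
        if np.any(np.diff(v) < 0):
            raise ValidationError("CDF boundary values must be nondecreasing")
        if np.any(v < 0) or np.any(v > 1):
            raise ValidationError("CDF boundary values must lie in [0, 1]")

    @classmethod
    def load_default(cls) -> "CdfBoundary":
        """Boundary calibrated on the default synthetic compositions (shipped)."""
        with resources.files("disevo.data").joinpath("cdf_boundary.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
        return cls(tuple(df["threshold"]), tuple(df["boundary"]))

    def save(self, path: str | Path, header: str = "") -> None:
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("threshold\tboundary\n")
            for t, v in zip(self.thresholds, self.values):
                fh.write(f"{t:g}\t{v:.6f}\n")


@dataclass(frozen=True)
class ChCdfPoint:
    """Whole-sequence CH-CDF summary for one protein."""

    protein_id: str
    mean_net_charge: float
    mean_hydropathy: float
    dch: float
    dcdf: float
    quadrant: str


def disorder_profile(
    record: ProteinRecord, window: int = DEFAULT_WINDOW, scale: str = "kyte-doolittle"
) -> DisorderProfile:
    """Fold-index stand-in disorder profile over a sliding window.

    The window is centered and shrunk symmetrically near the termini, so the
    effective half-width at position i is ``min(window//2, i, L-1-i)``.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be a positive odd integer, got {window}")
    if scale != "kyte-doolittle":
        raise ParameterError(f"unknown hydropathy scale {scale!r}")
    seq = record.sequence
    n = len(seq)
    h = np.array([normalized_hydropathy(c) for c in seq])
    q = np.array([residue_charge(c) for c in seq])
    ch = np.concatenate(([0.0], np.cumsum(h)))
    cq = np.concatenate(([0.0], np.cumsum(q)))
    idx = np.arange(n)
    half = np.minimum(window // 2, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - half, idx + half + 1
    width = (hi - lo).astype(float)
    mean_h = (ch[hi] - ch[lo]) / width
    mean_q = (cq[hi] - cq[lo]) / width
    fold_index = CH_SLOPE * mean_h - np.abs(mean_q) - CH_OFFSET
    scores = np.clip(0.5 - fold_index, 0.0, 1.0)
    return DisorderProfile(protein_id=record.id, scores=scores, window=window)


def ch_point(record: ProteinRecord) -> tuple[float, float, float]:
    """Whole-sequence CH-plot coordinates ``(R, H, dCH)``.

    R is the absolute mean net charge |#(K,R) - #(D,E)| / L, H the mean
    normalized hydropathy, and dCH the vertical distance from the boundary
    line; positive dCH = charge excess (disorder-prone side).
    """
    seq = record.sequence
    net = sum(residue_charge(c) for c in seq)
    r = abs(net) / len(seq)
    h = float(np.mean([normalized_hydropathy(c) for c in seq]))
    dch = r - (CH_SLOPE * h - CH_OFFSET)
    return r, h, dch


def cdf_distance(profile: DisorderProfile, boundary: CdfBoundary) -> float:
    """Signed mean distance of the score CDF from the boundary.

    CDF(t) is the fraction of residues with score <= t (right-continuous step
    function); dCDF = mean_i [CDF(t_i) - boundary_i]. Positive values are
    order-prone, negative disorder-prone.
    """
    t = np.asarray(boundary.thresholds, float)
    b = np.asarray(boundary.values, float)
    cdf = np.array([np.mean(profile.scores <= ti) for ti in t])
    return float(np.mean(cdf - b))


def calibrate_cdf_boundary(
    ordered_set: Sequence[DisorderProfile],
    disordered_set: Sequence[DisorderProfile],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> CdfBoundary:
    """Midpoint boundary between the mean CDF curves of two reference classes.

    At each threshold the boundary is the midpoint of the ordered-class and
    disordered-class mean CDFs, made nondecreasing by a cumulative maximum.
    """
    if not ordered_set or not disordered_set:
        raise ParameterError("both calibration classes must be non-empty")
    t = np.asarray(thresholds, float)

    def mean_cdf(profiles: Sequence[DisorderProfile]) -> np.ndarray:
        curves = [
            np.array([np.mean(p.scores <= ti) for ti in t]) for p in profiles
        ]
        return np.mean(curves, axis=0)

    mid = (mean_cdf(ordered_set) + mean_cdf(disordered_set)) / 2.0
    mid = np.maximum.accumulate(mid)
    return CdfBoundary(tuple(t), tuple(np.clip(mid, 0.0, 1.0)))


def classify_quadrant(dch: float, dcdf: float) -> str:
    """Quadrant of the CH-CDF plane under the >= 0 boundary convention."""
    if dch >= 0 and dcdf >= 0:
        return "Q1"
    if dch < 0 and dcdf >= 0:
        return "Q2"
    if dch < 0 and dcdf < 0:
        return "Q3"
    return "Q4"


def chcdf_point(
    record: ProteinRecord,
    boundary: CdfBoundary,
    window: int = DEFAULT_WINDOW,
    profile: DisorderProfile | None = None,
) -> ChCdfPoint:
    """Full CH-CDF summary (CH coordinates, dCDF, quadrant) for one protein."""
    if profile is None:
        profile = disorder_profile(record, window=window)
    r, h, dch = ch_point(record)
    dcdf = cdf_distance(profile, boundary)
    return ChCdfPoint(
        protein_id=record.id,
        mean_net_charge=r,
        mean_hydropathy=h,
        dch=dch,
        dcdf=dcdf,
        quadrant=classify_quadrant(dch, dcdf),
    )


def chcdf_table(
    records: Sequence[ProteinRecord],
    boundary: CdfBoundary,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-protein CH-CDF table (id, species, group, R, H, dCH, dCDF, quadrant)."""
    rows = []
    for rec in records:
        prof = disorder_profile(rec, window=window)
        pt = chcdf_point(rec, boundary, window=window, profile=prof)
        rows.append(
            {
                "id": rec.id,
                "species": rec.species,
                "group": rec.group,
                "mean_net_charge": pt.mean_net_charge,
                "mean_hydropathy": pt.mean_hydropathy,
                "dCH": pt.dch,
                "dCDF": pt.dcdf,
                "quadrant": pt.quadrant,
                "fraction_disordered": prof.fraction_disordered,
            }
        )
    return pd.DataFrame(rows)


def domain_mean_disorder(profile: DisorderProfile, region: DomainAnnotation) -> float:
    """Arithmetic mean disorder score over a region of the profile."""
    start, end = region.interval
    if end > len(profile):
        raise ValidationError(
            f"region {region.domain_name!r} ({region.start}-{region.end}) exceeds "
            f"profile length {len(profile)}"
        )
    return float(np.mean(profile.scores[start:end]))


def group_domain_disorder(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, DisorderProfile],
    regions: Mapping[str, Iterable[DomainAnnotation]],
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean per-domain disorder per species group (tidy table).

    Each cell averages :func:`domain_mean_disorder` over the proteins of one
    group that carry the domain; proteins lacking the domain are excluded from
    the cell and the contributing count ``n`` is reported. Groups with no
    contributing protein yield NaN, never zero.
    """
    per_protein: list[tuple[str, str, float]] = []
    domains: list[str] = []
    for rec in records:
        for region in regions.get(rec.id, ()):
            if region.domain_name not in domains:
                domains.append(region.domain_name)
            per_protein.append(
                (rec.group, region.domain_name, domain_mean_disorder(profiles[rec.id], region))
            )
    groups = group_order if group_order is not None else sorted({r.group for r in records})
    rows = []
    for grp in groups:
        for dom in domains:
            vals = [v for g, d, v in per_protein if g == grp and d == dom]
            rows.append(
                {
                    "group": grp,
                    "domain": dom,
                    "mean_disorder": float(np.mean(vals)) if vals else float("nan"),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)
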