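"""Blue-native co-fractionation: profile normalization, consensus,
co-elution correlation, and candidate-pair filtering.

Intact complexes co-migrate through a native gel, so subunits share
elution profiles across the 48 fractions (fraction 1 = highest apparent
mass). Candidate pairs pass when their co-elution score reaches 0.7 in at
least two replicates, their complex has at most 25 proteins, and the
complex peak elutes at an apparent mass of at least 67 kDa (via a marker
calibration). When no external score column is supplied the per-replicate
score defaults to max(0, Pearson r) of the replicate profiles — a stand-in
for an upstream co-fractionation classifier, not a re-implementation.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_FRACTIONS = 48
SCORE_MIN = 0.7
MIN_REPLICATES = 2
MAX_COMPLEX_SIZE = 25
MIN_PEAK_MASS_KDA = 67.0


def normalize_profile(raw: np.ndarray | pd.Series, mode: str = "sum"):
    """Normalize one elution profile; sum-mode sums to 1, max-mode peaks at 1.

    All-zero profiles cannot be normalized and raise; callers should flag
    and exclude them from correlation. Idempotent in both modes.
    """
    x = np.asarray(raw, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensities must be non-negative")
    denom = x.sum() if mode == "sum" else x.max()
    if mode not in ("sum", "max"):
        raise ValueError(f"unknown mode {mode!r}")
    if denom <= 0:
        raise ValueError("all-zero profile cannot be normalized")
    out = x / denom
    if isinstance(raw, pd.Series):
        return pd.Series(out, index=raw.index, name=raw.name)
    return out


def normalize_profiles(matrix: pd.DataFrame, mode: str = "sum"
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Normalize a proteins × fractions matrix row-wise.

    Returns (normalized matrix, list of all-zero accessions excluded).
    """
    flagged = [str(i) for i in matrix.index[matrix.sum(axis=1) <= 0]]
    keep = matrix.loc[matrix.sum(axis=1) > 0]
    denom = keep.sum(axis=1) if mode == "sum" else keep.max(axis=1)
    return keep.div(denom, axis=0), flagged


def consensus_profile(
    replicates: pd.DataFrame, r_floor: float = 0.5
) -> tuple[pd.Series, list]:
    """Mean profile across replicates with outlier exclusion.

    The replicate most dissimilar (lowest Pearson r) to the per-fraction
    median profile is dropped when its r falls below ``r_floor``; the mean
    of the remainder is returned along with the dropped replicate ids.
    With a single replicate the profile passes through with a warning.
    A fraction-level variant is available via :func:`consensus_profile_fractionwise`.
    """
    if len(replicates) < 2:
        warnings.warn("consensus from a single replicate: passthrough")
        return replicates.iloc[0], []
    median = replicates.median(axis=0)
    rs = {}
    for rep, prof in replicates.iterrows():
        with np.errstate(invalid="ignore"):
            r = _pearson(prof.to_numpy(), median.to_numpy())
        rs[rep] = -np.inf if np.isnan(r) else r
    worst = min(rs, key=lambda k: (rs[k], str(k)))
    dropped = []
    if rs[worst] < r_floor and len(replicates) > 1:
        dropped = [worst]
    keep = replicates.drop(index=dropped)
    if len(keep) == 0:
        keep = replicates
        dropped = []
    return keep.mean(axis=0), dropped


def consensus_profile_fractionwise(replicates: pd.DataFrame) -> pd.Series:
    """Fraction-level outlier variant: per fraction, drop the single most
    median-dissimilar replicate value, then average the rest."""
    median = replicates.median(axis=0)
    dev = (replicates - median).abs()
    out = {}
    for col in replicates.columns:
        vals = replicates[col]
        worst = dev[col].idxmax()
        out[col] = vals.drop(index=worst).mean() if len(vals) > 1 else vals.iloc[0]
    return pd.Series(out)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def coelution_correlation(
    profiles: pd.DataFrame, pairs: Iterable[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson r of consensus profiles for each requested pair.

    Zero-variance profiles make r undefined; such pairs are flagged with
    NaN rather than dropped.
    """
    rows = []
    for a, b in pairs:
        r = np.nan
        flagged = True
        if a in profiles.index and b in profiles.index:
            r = _pearson(
                profiles.loc[a].to_numpy(dtype=float),
                profiles.loc[b].to_numpy(dtype=float),
            )
            flagged = bool(np.isnan(r))
        rows.append({"accession_a": a, "accession_b": b, "r": r,
                     "flagged": flagged})
    return pd.DataFrame(rows, columns=["accession_a", "accession_b", "r",
                                       "flagged"])


def scores_from_replicates(
    replicate_profiles: Mapping[int, pd.DataFrame],
    pairs: Iterable[tuple[str, str]],
    mode: str = "sum",
) -> pd.DataFrame:
    """Default per-replicate co-elution score: max(0, Pearson r).

    Used when no external classifier score table is provided. Returns a
    long frame (accession_a, accession_b, replicate, score).
    """
    rows = []
    pairs = list(pairs)
    for rep, matrix in sorted(replicate_profiles.items()):
        norm, _ = normalize_profiles(matrix, mode=mode)
        corr = coelution_correlation(norm, pairs)
        for rec in corr.itertuples(index=False):
            score = 0.0 if np.isnan(rec.r) else max(0.0, rec.r)
            rows.append(
                {"accession_a": rec.accession_a, "accession_b": rec.accession_b,
                 "replicate": rep, "score": score}
            )
    return pd.DataFrame(rows)


def complex_peak_mass(
    profile: pd.Series, calibration: pd.DataFrame | None
) -> float | None:
    """Apparent mass (kDa) at a consensus profile's peak fraction.

    ``calibration`` maps fraction → kDa for the native markers; apparent
    mass between markers is interpolated on a log scale. Returns None
    when no calibration is supplied.
    """
    if calibration is None:
        return None
    peak_fraction = int(str(profile.idxmax()).rsplit("_", 1)[-1]) \
        if isinstance(profile.idxmax(), str) else int(profile.idxmax())
    cal = calibration.sort_values("fraction")
    log_mass = np.interp(
        peak_fraction, cal["fraction"], np.log10(cal["kda"])
    )
    return float(10 ** log_mass)


def filter_bn_candidates(
    candidates: pd.DataFrame,
    score_min: float = SCORE_MIN,
    min_replicates: int = MIN_REPLICATES,
    max_complex_size: int = MAX_COMPLEX_SIZE,
    min_peak_mass_kda: float = MIN_PEAK_MASS_KDA,
    calibration_available: bool = True,
) -> pd.DataFrame:
    """Apply the replicate-consensus and complex-level filters.

    ``candidates`` is one row per pair with columns: accession_a,
    accession_b, a ``scores`` list (or rep_* columns) of per-replicate
    co-elution scores, complex_size, peak_mass_kda. A pair passes iff its
    score is ≥ ``score_min`` in ≥ ``min_replicates`` replicates AND its
    complex has ≤ ``max_complex_size`` proteins AND the complex peak
    apparent mass is ≥ ``min_peak_mass_kda``. Without calibration the mass
    filter is skipped with a warning. The filter is monotone: raising any
    replicate score never flips pass → fail.
    """
    df = candidates.copy()
    if "scores" in df.columns:
        score_lists = df["scores"]
    else:
        rep_cols = [c for c in df.columns if c.startswith("rep_")]
        score_lists = df[rep_cols].values.tolist()
    n_passing = [
        int(sum(s >= score_min for s in scores if not pd.isna(s)))
        for scores in score_lists
    ]
    df["bn_replicates_passing"] = n_passing
    ok_score = df["bn_replicates_passing"] >= min_replicates
    ok_size = df["complex_size"] <= max_complex_size
    if calibration_available and "peak_mass_kda" in df.columns \
            and df["peak_mass_kda"].notna().any():
        ok_mass = df["peak_mass_kda"] >= min_peak_mass_kda
    else:
        warnings.warn("no mass calibration: peak-mass filter skipped")
        ok_mass = pd.Series(True, index=df.index)
    df["passes_filters"] = ok_score & ok_size & ok_mass
    return df
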