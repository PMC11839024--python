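"""Cross-link table processing.

Search-engine output rows (protein accessions, 1-based residue positions,
linker chemistry, score, replicate) are canonicalized and deduplicated,
checked against membrane-topology annotations, collapsed to protein-pair
interactions, and secondary-chemistry links (DHSO acid–acid, DMTMM
acid–Lys) are mapped onto the DSSO-defined interaction set. Upstream FDR
control is assumed already applied; the search engine is carried as
metadata only.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

XL_SCORE_MIN = 40.0

LINK_KEY = ["accession_a", "pos_a", "accession_b", "pos_b", "chemistry"]


def canonicalize(links: pd.DataFrame) -> pd.DataFrame:
    """Order each link so accession_a ≤ accession_b (and pos_a ≤ pos_b for
    intra-links), making duplicates collapse deterministically."""
    df = links.copy()
    swap = (df["accession_a"] > df["accession_b"]) | (
        (df["accession_a"] == df["accession_b"]) & (df["pos_a"] > df["pos_b"])
    )
    for a, b in (("accession_a", "accession_b"), ("pos_a", "pos_b")):
        df.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
    return df


def dedup_and_filter(
    raw: pd.DataFrame, score_min: float = XL_SCORE_MIN
) -> tuple[pd.DataFrame, dict]:
    """Collapse raw rows to unique residue-pair links above the score cut.

    Rows with score strictly greater than ``score_min`` survive (a score
    exactly at the threshold is removed). One row per canonical
    (accession_a, pos_a, accession_b, pos_b, chemistry) is kept with the
    best score and the count of distinct replicates. Malformed positions
    (missing, non-integer, < 1) are rejected and counted in the report.
    """
    df = raw.copy()
    pos_ok = pd.Series(True, index=df.index)
    for col in ("pos_a", "pos_b"):
        as_num = pd.to_numeric(df[col], errors="coerce")
        pos_ok &= as_num.notna() & (as_num >= 1) & (as_num == as_num.round())
        df[col] = as_num
    n_malformed = int((~pos_ok).sum())
    if n_malformed:
        logger.warning("rejected %d rows with malformed positions", n_malformed)
    df = df[pos_ok].copy()
    df["pos_a"] = df["pos_a"].astype(int)
    df["pos_b"] = df["pos_b"].astype(int)
    df = df[pd.to_numeric(df["score"], errors="coerce") > score_min]
    df = canonicalize(df)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    grouped = df.groupby(LINK_KEY, as_index=False).agg(
        score=("score", "max"),
        n_replicates=("replicate", "nunique"),
        n_rows=("score", "size"),
    )
    grouped["is_intra"] = grouped["accession_a"] == grouped["accession_b"]
    grouped = grouped.sort_values(LINK_KEY).reset_index(drop=True)
    report = {
        "n_raw": len(raw),
        "n_malformed": n_malformed,
        "n_below_score": int(len(raw) - n_malformed - len(df)),
        "n_unique": len(grouped),
    }
    return grouped, report


# ---------------------------------------------------------------------------
# Topology


def _classify_residue(
    pos: int, segments: pd.DataFrame
) -> str | None:
    """Compartment class of one residue given its protein's segments.

    A residue inside a transmembrane segment is classed by its nearest
    flanking compartment (linker lysines at TM borders are chemically
    accessible from the flanking region). Residues in no segment are
    unannotated (None).
    """
    hit = segments[(segments["start"] <= pos) & (pos <= segments["end"])]
    if hit.empty:
        return None
    cls = hit.iloc[0]["compartment"]
    if cls != "TM":
        return cls
    non_tm = segments[segments["compartment"] != "TM"]
    if non_tm.empty:
        return None
    gaps = np.minimum(
        np.abs(non_tm["start"].to_numpy() - pos),
        np.abs(non_tm["end"].to_numpy() - pos),
    )
    return str(non_tm.iloc[int(np.argmin(gaps))]["compartment"])


def topology_check(
    links: pd.DataFrame, annotations: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Verdict per link: consistent / inconsistent / unannotated.

    A link is consistent when both residues fall in segments of the same
    compartment side: cytosolic with cytosolic, and lumenal/extracellular
    grouped together as the non-cytosolic side. Links with an unannotated
    residue are excluded from the consistency percentage.
    """
    seg_by_acc = {acc: grp for acc, grp in annotations.groupby("accession")}

    def side(cls: str | None) -> str | None:
        if cls is None:
            return None
        return "cytosolic" if cls == "cytosolic" else "non-cytosolic"

    verdicts = []
    for rec in links.itertuples(index=False):
        segs_a = seg_by_acc.get(rec.accession_a)
        segs_b = seg_by_acc.get(rec.accession_b)
        cls_a = _classify_residue(int(rec.pos_a), segs_a) if segs_a is not None else None
        cls_b = _classify_residue(int(rec.pos_b), segs_b) if segs_b is not None else None
        sa, sb = side(cls_a), side(cls_b)
        if sa is None or sb is None:
            verdicts.append("unannotated")
        elif sa == sb:
            verdicts.append("consistent")
        else:
            verdicts.append("inconsistent")
    out = links.copy()
    out["topology"] = verdicts
    annotated = out[out["topology"] != "unannotated"]
    frac = (
        float((annotated["topology"] == "consistent").mean())
        if len(annotated)
        else None
    )
    report = {
        "n_links": len(out),
        "n_consistent": int((out["topology"] == "consistent").sum()),
        "n_inconsistent": int((out["topology"] == "inconsistent").sum()),
        "n_unannotated": int((out["topology"] == "unannotated").sum()),
        "fraction_consistent": frac,
    }
    return out, report


# ---------------------------------------------------------------------------
# Pair collapse and secondary-chemistry mapping


def collapse_to_pairs(links: pd.DataFrame) -> pd.DataFrame:
    """Collapse unique residue-pair links to protein-pair interactions.

    Inter-protein links define hetero edges with ``xl_count`` = number of
    unique residue pairs; intra-protein links are recorded as self-evidence
    rows (``is_self`` = True) and define no hetero edge.
    """
    df = canonicalize(links)
    grouped = df.groupby(["accession_a", "accession_b"], as_index=False).agg(
        xl_count=("pos_a", "size"),
        best_score=("score", "max"),
    )
    grouped["is_self"] = grouped["accession_a"] == grouped["accession_b"]
    return grouped.sort_values(["accession_a", "accession_b"]).reset_index(drop=True)


def map_secondary_chemistry(
    secondary: pd.DataFrame,
    primary_pairs: Iterable[tuple[str, str]],
    ambiguity_groups: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map DHSO/DMTMM links onto the DSSO-defined interaction set.

    Each secondary link's accessions are expanded through their peptide
    ambiguity groups (shared peptide sequences make a link attributable to
    several paralogs); the link annotates every primary interaction whose
    pair can be formed from the expansions — possibly several. Returns
    (matches, unmatched links).
    """
    groups = {k: list(v) for k, v in (ambiguity_groups or {}).items()}

    def expand(acc: str) -> list[str]:
        out = {acc}
        out.update(groups.get(acc, []))
        return sorted(out)

    primary = {tuple(sorted(p)) for p in primary_pairs}
    match_rows, unmatched_rows = [], []
    for idx, rec in enumerate(secondary.itertuples(index=False)):
        hits = set()
        for a in expand(rec.accession_a):
            for b in expand(rec.accession_b):
                pair = tuple(sorted((a, b)))
                if pair in primary:
                    hits.add(pair)
        if hits:
            for pair in sorted(hits):
                match_rows.append(
                    {
                        "link_index": idx,
                        "accession_a": rec.accession_a,
                        "pos_a": rec.pos_a,
                        "accession_b": rec.accession_b,
                        "pos_b": rec.pos_b,
                        "chemistry": rec.chemistry,
                        "matched_a": pair[0],
                        "matched_b": pair[1],
                    }
                )
        else:
            unmatched_rows.append(
                {
                    "link_index": idx,
                    "accession_a": rec.accession_a,
                    "pos_a": rec.pos_a,
                    "accession_b": rec.accession_b,
                    "pos_b": rec.pos_b,
                    "chemistry": rec.chemistry,
                }
            )
    cols = ["link_index", "accession_a", "pos_a", "accession_b", "pos_b",
            "chemistry"]
    matches = pd.DataFrame(match_rows, columns=cols + ["matched_a", "matched_b"])
    unmatched = pd.DataFrame(unmatched_rows, columns=cols)
    return matches, unmatched
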