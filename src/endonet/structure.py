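"""Structural models and cross-link distance constraints.

A :class:`StructureModel` holds per-chain Cα coordinates with per-residue
confidence (pLDDT, 0-100) and a chain→(accession, offset) map reconciling
structure-internal numbering with full-length sequence positions.
Cross-links are evaluated against a maximum Cα–Cα distance compatible with
the linker arm: 35 Å for standard predictions and experimental structures,
30 Å for link-assisted predictions whose inference already consumed the
links. Residues with pLDDT ≤ 70 are treated as unstructured and excluded
from the distance statistics; experimental structures carry no pLDDT and
skip the gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

#: Default maximum Cα–Cα distance (Å) by (chemistry, model source class).
#: Link-assisted predictions use the stricter 30 Å for every chemistry.
DEFAULT_DISTANCE_MATRIX: dict[tuple[str, str], float] = {
    ("DSSO", "pairwise-prediction"): 35.0,
    ("DSSO", "PDB"): 35.0,
    ("DSSO", "synthetic"): 35.0,
    ("DMTMM", "pairwise-prediction"): 35.0,
    ("DMTMM", "PDB"): 35.0,
    ("DMTMM", "synthetic"): 35.0,
    ("DHSO", "pairwise-prediction"): 35.0,
    ("DHSO", "PDB"): 35.0,
    ("DHSO", "synthetic"): 35.0,
    ("DSSO", "link-assisted-prediction"): 30.0,
    ("DMTMM", "link-assisted-prediction"): 30.0,
    ("DHSO", "link-assisted-prediction"): 30.0,
}

PLDDT_MIN = 70.0
SPOC_MIN = 0.33
TRIMER_INTERFACE_MIN = 0.5
CONTACT_CUTOFF = 8.0
VARIANT_WINDOW = 2


@dataclass
class Chain:
    """Ordered residues of one chain: Cα coordinates and confidence."""

    coords: np.ndarray  # (n, 3) float, Å; NaN rows mark missing Cα
    plddt: np.ndarray | None = None  # (n,) in [0, 100], None for experimental

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
            if self.plddt.shape[0] != self.coords.shape[0]:
                raise ValueError("plddt length must match coords")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass
class StructureModel:
    """Cα-level structural model with chain→accession mapping.

    ``chain_map[chain] = (accession, offset)``: structure residue 1 of the
    chain corresponds to full-length position ``offset + 1``.
    """

    model_id: str
    source: str  # {PDB|pairwise-prediction|link-assisted-prediction|synthetic}
    chains: dict[str, Chain]
    chain_map: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        missing = set(self.chain_map) - set(self.chains)
        if missing:
            raise ValueError(f"chain_map references absent chains: {sorted(missing)}")

    @property
    def accessions(self) -> list[str]:
        return [acc for acc, _ in self.chain_map.values()]

    def chains_for(self, accession: str) -> list[str]:
        return [c for c, (acc, _) in self.chain_map.items() if acc == accession]

    def resolve(self, accession: str, position: int) -> tuple[str, int] | None:
        """Map a full-length position to (chain, 0-based residue index).

        Returns None when the position falls outside every modeled chain of
        the accession.
        """
        for chain_id, (acc, offset) in self.chain_map.items():
            if acc != accession:
                continue
            idx = position - offset - 1
            if 0 <= idx < len(self.chains[chain_id]):
                return chain_id, idx
        return None

    def full_length_positions(self, chain_id: str) -> np.ndarray:
        acc, offset = self.chain_map[chain_id]
        return np.arange(1, len(self.chains[chain_id]) + 1) + offset


# ---------------------------------------------------------------------------
# mmCIF / PDB I/O


def write_mmcif(model: StructureModel, path: str | Path) -> Path:
    """Write a Cα-only mmCIF file; pLDDT goes to the B-factor column."""
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for chain_id, chain in model.chains.items():
        gc = gemmi.Chain(chain_id)
        for i in range(len(chain)):
            if not np.all(np.isfinite(chain.coords[i])):
                continue
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*chain.coords[i])
            atom.b_iso = float(chain.plddt[i]) if chain.plddt is not None else 0.0
            atom.occ = 1.0
            res.add_atom(atom)
            gc.add_residue(res)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    st.make_mmcif_document().write_file(str(path))
    return path


def load_structure(
    path: str | Path,
    chain_map: Mapping[str, tuple[str, int]],
    source: str = "pairwise-prediction",
    model_id: str | None = None,
) -> StructureModel:
    """Load Cα coordinates from mmCIF/PDB into a :class:`StructureModel`.

    The B-factor column is read as pLDDT for predicted models. Residues
    lacking a Cα atom get NaN coordinates and are later reported as
    unmapped. Chains named in ``chain_map`` but absent from the file are an
    error naming the chain.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    gm = st[0]
    present = {ch.name for ch in gm}
    missing = set(chain_map) - present
    if missing:
        raise ValueError(
            f"chain(s) {sorted(missing)} in chain_map not present in {path}"
        )
    chains: dict[str, Chain] = {}
    has_plddt = source != "PDB"
    for ch in gm:
        if ch.name not in chain_map:
            continue
        n = max(res.seqid.num for res in ch)
        coords = np.full((n, 3), np.nan)
        plddt = np.zeros(n) if has_plddt else None
        for res in ch:
            ca = res.find_atom("CA", "*")
            idx = res.seqid.num - 1
            if ca is not None:
                coords[idx] = [ca.pos.x, ca.pos.y, ca.pos.z]
                if plddt is not None:
                    plddt[idx] = ca.b_iso
        chains[ch.name] = Chain(coords=coords, plddt=plddt)
    return StructureModel(
        model_id=model_id or st.name or Path(path).stem,
        source=source,
        chains=chains,
        chain_map=dict(chain_map),
    )


# ---------------------------------------------------------------------------
# Distances


def ca_distance(
    model: StructureModel, ref_a: tuple[str, int], ref_b: tuple[str, int]
) -> float:
    """Euclidean Cα–Cα distance (Å) between two (accession, position) refs.

    Raises KeyError when a residue cannot be mapped to coordinates.
    """
    ra = model.resolve(*ref_a)
    rb = model.resolve(*ref_b)
    if ra is None or rb is None:
        raise KeyError(f"unmapped residue: {ref_a if ra is None else ref_b}")
    ca = model.chains[ra[0]].coords[ra[1]]
    cb = model.chains[rb[0]].coords[rb[1]]
    if not (np.all(np.isfinite(ca)) and np.all(np.isfinite(cb))):
        raise KeyError("residue lacks Cα coordinates")
    return float(math.dist(ca, cb))


def _lookup_threshold(
    chemistry: str, source: str, matrix: Mapping[tuple[str, str], float]
) -> float:
    if (chemistry, source) in matrix:
        return matrix[(chemistry, source)]
    if source == "link-assisted-prediction":
        return 30.0
    return 35.0


def evaluate_crosslinks(
    model: StructureModel,
    links: pd.DataFrame,
    threshold: float | None = None,
    plddt_min: float = PLDDT_MIN,
    distance_matrix: Mapping[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Evaluate Cα–Cα distance constraints for a table of cross-links.

    ``links`` needs columns accession_a, pos_a, accession_b, pos_b and
    optionally chemistry (default DSSO). Status per link:

    - ``unmapped``  — a residue falls outside the modeled range or has no Cα;
    - ``unstructured`` — mapped but either residue pLDDT ≤ ``plddt_min``
      (confidence gate skipped for experimental structures without pLDDT);
    - ``within``    — distance ≤ threshold;
    - ``exceeded``  — distance > threshold.

    The summary reports the fraction within among {within ∪ exceeded},
    separately for intra- and inter-protein links; zero-denominator
    fractions are reported as None.
    """
    matrix = dict(distance_matrix or DEFAULT_DISTANCE_MATRIX)
    rows = []
    for rec in links.itertuples(index=False):
        chem = getattr(rec, "chemistry", "DSSO")
        thr = threshold if threshold is not None else _lookup_threshold(
            chem, model.source, matrix
        )
        ref_a = (rec.accession_a, int(rec.pos_a))
        ref_b = (rec.accession_b, int(rec.pos_b))
        is_intra = rec.accession_a == rec.accession_b
        ra = model.resolve(*ref_a)
        rb = model.resolve(*ref_b)
        dist = np.nan
        min_plddt = np.nan
        if ra is None or rb is None:
            status = "unmapped"
        else:
            ca = model.chains[ra[0]].coords[ra[1]]
            cb = model.chains[rb[0]].coords[rb[1]]
            if not (np.all(np.isfinite(ca)) and np.all(np.isfinite(cb))):
                status = "unmapped"
            else:
                dist = float(math.dist(ca, cb))
                pl_a = model.chains[ra[0]].plddt
                pl_b = model.chains[rb[0]].plddt
                if pl_a is not None and pl_b is not None:
                    min_plddt = float(min(pl_a[ra[1]], pl_b[rb[1]]))
                    gated = min_plddt <= plddt_min
                else:
                    gated = False  # experimental model: no confidence gate
                if gated:
                    status = "unstructured"
                elif dist <= thr:
                    status = "within"
                else:
                    status = "exceeded"
        rows.append(
            {
                "accession_a": rec.accession_a,
                "pos_a": int(rec.pos_a),
                "accession_b": rec.accession_b,
                "pos_b": int(rec.pos_b),
                "chemistry": chem,
                "is_intra": is_intra,
                "distance": dist,
                "status": status,
                "threshold_used": thr,
                "min_plddt_of_pair": min_plddt,
            }
        )
    cols = [
        "accession_a", "pos_a", "accession_b", "pos_b", "chemistry",
        "is_intra", "distance", "status", "threshold_used",
        "min_plddt_of_pair",
    ]
    evals = pd.DataFrame(rows, columns=cols)
    evals["is_intra"] = evals["is_intra"].astype(bool)  # keep dtype on empty

    def _frac(sub: pd.DataFrame) -> float | None:
        measured = sub[sub["status"].isin(["within", "exceeded"])]
        if len(measured) == 0:
            return None
        return float((measured["status"] == "within").mean())

    summary = {
        "n_links": len(evals),
        "n_within": int((evals["status"] == "within").sum()),
        "n_exceeded": int((evals["status"] == "exceeded").sum()),
        "n_unstructured": int((evals["status"] == "unstructured").sum()),
        "n_unmapped": int((evals["status"] == "unmapped").sum()),
        "fraction_within": _frac(evals),
        "fraction_within_intra": _frac(evals[evals["is_intra"]]),
        "fraction_within_inter": _frac(evals[~evals["is_intra"]]),
    }
    return evals, summary


# ---------------------------------------------------------------------------
# Prediction triage


def classify_prediction(
    spoc: float | None,
    evaluations: pd.DataFrame,
    spoc_min: float = SPOC_MIN,
    majority: float = 0.5,
    iptm: float | None = None,
) -> str:
    """Triage one pairwise prediction against its interprotein cross-links.

    Low-confidence when SPOC ≤ ``spoc_min`` (strictly greater is required to
    pass). Records without SPOC fall back to ipTM against the same
    threshold; with neither score the record is ``unscored``. Among scored
    records, the verdict comes from gated interprotein links: ``supported``
    when more than ``majority`` of measured links are within the constraint,
    ``unstructured-only`` when every link sits in unstructured or unmapped
    regions, ``violated`` otherwise.
    """
    score = spoc if spoc is not None and not pd.isna(spoc) else None
    if score is None:
        score = iptm if iptm is not None and not pd.isna(iptm) else None
        if score is None:
            return "unscored"
    if score <= spoc_min:
        return "low-confidence"
    inter = evaluations[~evaluations["is_intra"]]
    measured = inter[inter["status"].isin(["within", "exceeded"])]
    if len(inter) == 0:
        return "unstructured-only"
    if len(measured) == 0:
        return "unstructured-only"
    frac = (measured["status"] == "within").mean()
    return "supported" if frac > majority else "violated"


def trimer_quality(
    interface_scores: Sequence[float | None],
    interface_min: float = TRIMER_INTERFACE_MIN,
) -> bool:
    """Accept a trimer when ≥ 2 of its 3 interface averages are > 0.5 (strict).

    Missing interface scores count as 0.
    """
    scores = [0.0 if s is None or pd.isna(s) else float(s) for s in interface_scores]
    if len(scores) != 3:
        raise ValueError("a trimer has exactly 3 pairwise interfaces")
    return sum(s > interface_min for s in scores) >= 2


# ---------------------------------------------------------------------------
# Interfaces and variants


def contact_residues(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    contact_cutoff: float = CONTACT_CUTOFF,
) -> dict[str, set[int]]:
    """Inter-chain contact positions at a Cα–Cα cutoff, per accession.

    Returns {accession: set of full-length positions} for both chains.
    Cα-only models are the common case, hence the Cα–Cα criterion.
    """
    ca = model.chains[chain_a].coords
    cb = model.chains[chain_b].coords
    ok_a = np.all(np.isfinite(ca), axis=1)
    ok_b = np.all(np.isfinite(cb), axis=1)
    diff = ca[:, None, :] - cb[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    dist[~ok_a, :] = np.inf
    dist[:, ~ok_b] = np.inf
    in_contact = dist <= contact_cutoff
    pos_a = model.full_length_positions(chain_a)
    pos_b = model.full_length_positions(chain_b)
    acc_a = model.chain_map[chain_a][0]
    acc_b = model.chain_map[chain_b][0]
    out: dict[str, set[int]] = {acc_a: set(), acc_b: set()}
    out[acc_a].update(int(p) for p in pos_a[in_contact.any(axis=1)])
    out[acc_b].update(int(p) for p in pos_b[in_contact.any(axis=0)])
    return out


def variant_interface_scan(
    variants: pd.DataFrame,
    contacts: Mapping[str, Iterable[int]],
    window: int = VARIANT_WINDOW,
) -> pd.DataFrame:
    """Flag variants within ``window`` residues of an interface contact.

    Sequence distance only: a variant hits when its protein has a contact
    position within ``window`` of the variant position. Adds columns
    near_interface, nearest_contact and gap.
    """
    contact_arrays = {
        acc: np.array(sorted(set(int(p) for p in pos)), dtype=int)
        for acc, pos in contacts.items()
    }
    out = variants.copy()
    near, nearest, gaps = [], [], []
    for rec in out.itertuples(index=False):
        arr = contact_arrays.get(rec.accession)
        if arr is None or arr.size == 0:
            near.append(False)
            nearest.append(np.nan)
            gaps.append(np.nan)
            continue
        d = np.abs(arr - int(rec.position))
        i = int(np.argmin(d))
        near.append(bool(d[i] <= window))
        nearest.append(int(arr[i]))
        gaps.append(int(d[i]))
    out["near_interface"] = near
    out["nearest_contact"] = nearest
    out["gap"] = gaps
    return out


# ---------------------------------------------------------------------------
# Visualization export

_STATUS_COLOR = {"within": "cornflower blue", "exceeded": "red"}


def export_pseudobonds(
    model: StructureModel, evaluations: pd.DataFrame, path: str | Path
) -> tuple[Path, int]:
    """Write a pseudobond file drawing each mapped link between Cα atoms.

    One line per mapped link: ``/CHAIN:RES@CA /CHAIN:RES@CA color``, colored
    by distance status. Unmapped links are skipped; their count is returned.
    Lines are emitted in a deterministic sorted order.
    """
    lines = []
    skipped = 0
    for rec in evaluations.itertuples(index=False):
        if rec.status == "unmapped":
            skipped += 1
            continue
        ra = model.resolve(rec.accession_a, int(rec.pos_a))
        rb = model.resolve(rec.accession_b, int(rec.pos_b))
        if ra is None or rb is None:
            skipped += 1
            continue
        color = _STATUS_COLOR.get(rec.status, "gray")
        lines.append(
            f"/{ra[0]}:{ra[1] + 1}@CA /{rb[0]}:{rb[1] + 1}@CA {color}"
        )
    lines.sort()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("; pseudobonds: cross-links on model " + model.model_id + "\n")
        for line in lines:
            fh.write(line + "\n")
    return path, skipped


def read_pseudobonds(path: str | Path) -> list[str]:
    """Parse a pseudobond file back into its bond lines (for round trips)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        out.append(line)
    return out
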