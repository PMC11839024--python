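"""Synthetic fixtures with planted ground truth for every pipeline stage.

The generators emulate the study conditions the pipeline was designed for:
a multi-study presence/absence matrix over candidate organelle proteins,
Gaussian co-elution peaks across 48 blue-native fractions, Cα-level
structural models with planted inter-chain contacts, cross-links drawn from
true contacts plus decoys, and variants placed near or far from interfaces.
Each generator draws from a named substream of a single integer seed, so
outputs are bit-identical under the same seed and independent of one
another.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from endonet.rng import substream
from endonet.structure import Chain, StructureModel, write_mmcif

COMPARTMENTS = ("endosome", "lysosome", "golgi", "mito", "nucleus", "other")

N_FRACTIONS = 48

#: Per-dataset detection probability by compartment class. Endosomal
#: proteins are detected in roughly half of the 16 emulated studies;
#: background proteins appear sporadically.
DEFAULT_SENSITIVITY = {
    "endosome": 0.5,
    "lysosome": 0.25,
    "golgi": 0.2,
    "mito": 0.12,
    "nucleus": 0.1,
    "other": 0.08,
}


@dataclass
class Complex:
    complex_id: str
    members: list[str]
    peak_fraction: float


@dataclass
class SyntheticWorld:
    """A fully specified ground-truth world for pipeline testing."""

    seed: int
    proteins: list[str]
    labels: dict[str, str]  # accession -> compartment
    complexes: list[Complex]
    structures: list[StructureModel] = field(default_factory=list)

    @property
    def endosomal(self) -> set[str]:
        return {p for p, c in self.labels.items() if c == "endosome"}


# ---------------------------------------------------------------------------
# Meta-analysis inputs


def gen_presence_matrix(
    n_proteins: int,
    n_datasets: int,
    sensitivity: Mapping[str, float] | None = None,
    seed: int = 0,
    class_fractions: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a presence/absence matrix across independent datasets.

    Each protein gets a compartment label; its row is i.i.d. Bernoulli with
    the per-class detection sensitivity. Returns (matrix, labels); labels
    support downstream ROC evaluation.
    """
    if n_proteins <= 0 or n_datasets < 2:
        raise ValueError("need n_proteins > 0 and n_datasets >= 2")
    sens = dict(DEFAULT_SENSITIVITY)
    if sensitivity:
        sens.update(sensitivity)
    for cls, p in sens.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"sensitivity for {cls} outside [0, 1]")
    fracs = dict(class_fractions or {
        "endosome": 0.15, "lysosome": 0.1, "golgi": 0.1,
        "mito": 0.15, "nucleus": 0.2, "other": 0.3,
    })
    rng = substream(seed, "presence_matrix")
    classes = list(fracs)
    probs = np.array([fracs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    labels = rng.choice(classes, size=n_proteins, p=probs)
    accs = [f"P{i:05d}" for i in range(n_proteins)]
    p_row = np.array([sens[c] for c in labels])
    mat = (rng.random((n_proteins, n_datasets)) < p_row[:, None]).astype(int)
    df = pd.DataFrame(
        mat, index=accs, columns=[f"dataset_{j + 1}" for j in range(n_datasets)]
    )
    return df, pd.Series(labels, index=accs, name="compartment")


def gen_meta_evidence(
    presence: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    abundance_shift: float = 1.5,
    interaction_rate: float = 3.0,
    reference_fraction: float = 0.5,
    missing_abundance_rate: float = 0.1,
) -> pd.DataFrame:
    """Derive the three meta-analysis metrics plus reference flags.

    dataset_presence counts the datasets identifying each protein;
    ip_abundance is log-scale with an additive shift for endosomal
    proteins (a fraction left missing, as in real IP data);
    ref_interaction_count is Poisson with a higher rate for endosomal
    proteins. A random half of the true endosomal proteins form the curated
    reference list; a small number of non-endosomal proteins are flagged
    mito-excludable.
    """
    rng = substream(seed, "meta_evidence")
    is_endo = (labels == "endosome").to_numpy()
    n = len(presence)
    abundance = rng.normal(5.0, 1.0, size=n) + abundance_shift * is_endo
    missing = rng.random(n) < missing_abundance_rate
    abundance[missing] = np.nan
    lam = np.where(is_endo, interaction_rate, 0.3)
    interactions = rng.poisson(lam)
    is_ref = np.zeros(n, dtype=bool)
    endo_idx = np.flatnonzero(is_endo)
    n_ref = max(1, int(round(reference_fraction * len(endo_idx))))
    if len(endo_idx):
        is_ref[rng.choice(endo_idx, size=min(n_ref, len(endo_idx)), replace=False)] = True
    is_mito = (labels == "mito").to_numpy()
    excludable = is_mito & (rng.random(n) < 0.1)
    return pd.DataFrame(
        {
            "accession": presence.index,
            "dataset_presence": presence.sum(axis=1).to_numpy(),
            "ip_abundance": abundance,
            "ref_interaction_count": interactions,
            "is_reference": is_ref,
            "is_mito_excludable": excludable,
            "true_endosomal": is_endo,
        }
    ).set_index("accession")


# ---------------------------------------------------------------------------
# Co-fractionation inputs


def gen_elution_profiles(
    complexes: Sequence[Complex],
    n_fractions: int = N_FRACTIONS,
    peak_width: float = 1.5,
    noise_cv: float = 0.1,
    n_replicates: int = 3,
    amplitude: float = 1e6,
    seed: int = 0,
) -> dict[int, pd.DataFrame]:
    """Simulate per-replicate elution intensity matrices.

    Every member of a complex shares the complex's Gaussian peak fraction;
    multiplicative noise with coefficient of variation ``noise_cv`` is
    applied per replicate. Returns {replicate: proteins × fractions frame}.
    """
    for cx in complexes:
        if not 1 <= cx.peak_fraction <= n_fractions:
            raise ValueError(
                f"complex {cx.complex_id} peak {cx.peak_fraction} outside "
                f"[1, {n_fractions}]"
            )
    rng = substream(seed, "elution_profiles")
    fractions = np.arange(1, n_fractions + 1, dtype=float)
    rows: dict[str, np.ndarray] = {}
    for cx in complexes:
        base = amplitude * np.exp(
            -0.5 * ((fractions - cx.peak_fraction) / peak_width) ** 2
        )
        for acc in cx.members:
            rows[acc] = base
    accs = list(rows)
    clean = np.vstack([rows[a] for a in accs])
    out: dict[int, pd.DataFrame] = {}
    for rep in range(1, n_replicates + 1):
        noisy = clean.copy()
        if noise_cv > 0:
            noisy = clean * np.clip(
                1.0 + noise_cv * rng.standard_normal(clean.shape), 0.0, None
            )
        out[rep] = pd.DataFrame(
            noisy, index=accs,
            columns=[f"fraction_{i}" for i in range(1, n_fractions + 1)],
        )
    return out


# ---------------------------------------------------------------------------
# Structures


def _ideal_helix(n: int, rise: float = 1.5, twist_deg: float = 100.0,
                 radius: float = 2.3) -> np.ndarray:
    """Ideal α-helix Cα trace: 1.5 Å rise, 100° twist per residue."""
    t = np.deg2rad(twist_deg) * np.arange(n)
    return np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)]
    )


def gen_structure(
    chain_lengths: Sequence[int],
    fold: str = "helix-bundle",
    plddt_profile: Sequence[np.ndarray] | None = None,
    seed: int = 0,
    chain_spacing: float = 8.0,
    chain_z_shift: float = 0.0,
    accessions: Sequence[str] | None = None,
    offsets: Sequence[int] | None = None,
    model_id: str = "synthetic-model",
) -> StructureModel:
    """Generate a synthetic Cα-level structure with attached confidence.

    ``helix-bundle`` lays ideal α-helices side by side ``chain_spacing`` Å
    apart; ``random-walk`` takes fixed 3.8 Å steps in random directions.
    Coordinates are quantized to 0.001 Å so mmCIF round-trips are exact.
    """
    if any(n < 5 for n in chain_lengths):
        raise ValueError("chain lengths must be >= 5")
    if fold not in ("helix-bundle", "random-walk"):
        raise ValueError(f"unknown fold {fold!r}")
    rng = substream(seed, "structure")
    chain_ids = [chr(ord("A") + i) for i in range(len(chain_lengths))]
    accessions = list(accessions or [f"SYN{i:03d}" for i in range(len(chain_lengths))])
    offsets = list(offsets or [0] * len(chain_lengths))
    chains: dict[str, Chain] = {}
    for i, (cid, n) in enumerate(zip(chain_ids, chain_lengths)):
        if fold == "helix-bundle":
            coords = _ideal_helix(n)
            coords[:, 0] += i * chain_spacing
            coords[:, 2] += i * chain_z_shift  # partial overlap → local interface
        else:
            steps = rng.standard_normal((n - 1, 3))
            steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
            coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
            coords[:, 0] += i * (3.8 * n + chain_spacing)
        coords = np.round(coords, 3)
        if plddt_profile is not None:
            plddt = np.asarray(plddt_profile[i], dtype=float)
            if plddt.shape[0] != n:
                raise ValueError("plddt_profile length mismatch")
        else:
            plddt = np.full(n, 90.0)
        chains[cid] = Chain(coords=coords, plddt=plddt)
    return StructureModel(
        model_id=model_id,
        source="synthetic",
        chains=chains,
        chain_map={c: (a, o) for c, a, o in zip(chain_ids, accessions, offsets)},
    )


# ---------------------------------------------------------------------------
# Cross-links


def _all_residue_pairs(model: StructureModel) -> pd.DataFrame:
    """Enumerate all residue pairs (intra within-chain and inter-chain)
    with their Cα–Cα distances, in full-length coordinates."""
    rows = []
    chain_ids = sorted(model.chains)
    for i, ca_id in enumerate(chain_ids):
        acc_a, _ = model.chain_map[ca_id]
        pos_a = model.full_length_positions(ca_id)
        xa = model.chains[ca_id].coords
        for cb_id in chain_ids[i:]:
            acc_b, _ = model.chain_map[cb_id]
            pos_b = model.full_length_positions(cb_id)
            xb = model.chains[cb_id].coords
            d = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2))
            if ca_id == cb_id:
                iu, ju = np.triu_indices(len(pos_a), k=1)
            else:
                iu, ju = np.meshgrid(
                    np.arange(len(pos_a)), np.arange(len(pos_b)), indexing="ij"
                )
                iu, ju = iu.ravel(), ju.ravel()
            for ii, jj in zip(iu, ju):
                rows.append(
                    (acc_a, int(pos_a[ii]), acc_b, int(pos_b[jj]),
                     float(d[ii, jj]), ca_id == cb_id)
                )
    return pd.DataFrame(
        rows,
        columns=["accession_a", "pos_a", "accession_b", "pos_b",
                 "distance", "is_intra"],
    )


def gen_crosslinks(
    model: StructureModel,
    n_true: int,
    n_decoy: int,
    true_max_dist: float = 35.0,
    seed: int = 0,
    chemistry: str = "DSSO",
    score_range: tuple[float, float] = (45.0, 120.0),
    inter_only: bool = False,
) -> pd.DataFrame:
    """Sample cross-links from a structure: true links from residue pairs
    within ``true_max_dist`` Å, decoys uniformly from the remaining pairs.

    Sampling is without replacement; if an eligible pool is smaller than
    requested, all of it is used and the shortfall is reported via a
    warning. A ``is_satisfiable`` ground-truth flag is attached.
    """
    pairs = _all_residue_pairs(model)
    if inter_only:
        pairs = pairs[~pairs["is_intra"]]
    rng = substream(seed, "crosslinks")
    true_pool = pairs[pairs["distance"] <= true_max_dist]
    decoy_pool = pairs[pairs["distance"] > true_max_dist]
    picks = []
    for pool, n_req, flag in ((true_pool, n_true, True), (decoy_pool, n_decoy, False)):
        if n_req == 0:
            continue
        if len(pool) < n_req:
            warnings.warn(
                f"requested {n_req} {'true' if flag else 'decoy'} links, "
                f"pool has {len(pool)}; generating all"
            )
            chosen = pool
        else:
            idx = rng.choice(len(pool), size=n_req, replace=False)
            chosen = pool.iloc[np.sort(idx)]
        chosen = chosen.copy()
        chosen["is_satisfiable"] = flag
        picks.append(chosen)
    if not picks:
        links = pairs.iloc[:0].copy()
        links["is_satisfiable"] = pd.Series(dtype=bool)
    else:
        links = pd.concat(picks, ignore_index=True)
    links["chemistry"] = chemistry
    lo, hi = score_range
    links["score"] = np.round(lo + (hi - lo) * rng.random(len(links)), 2)
    links["replicate"] = 1
    links["engine"] = "synthetic"
    return links.drop(columns=["distance"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Variants


def gen_variants(
    model: StructureModel,
    interface_contacts: Mapping[str, Sequence[int]],
    n_near: int,
    n_far: int,
    window: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Place variants near and far from interface contacts.

    Near variants land within ``window`` residues of some contact position
    of their protein; far variants land strictly outside every contact's
    window. A ground-truth ``true_near`` flag is attached. Raises when a
    requested placement is impossible.
    """
    contacts = {a: sorted(set(int(p) for p in ps))
                for a, ps in interface_contacts.items() if len(ps) > 0}
    if n_near > 0 and not contacts:
        raise ValueError("n_near > 0 requires a non-empty contact set")
    rng = substream(seed, "variants")
    near_pool, far_pool = [], []
    for chain_id, (acc, _) in sorted(model.chain_map.items()):
        positions = model.full_length_positions(chain_id)
        cpos = np.array(contacts.get(acc, []), dtype=int)
        for p in positions:
            if cpos.size and np.abs(cpos - p).min() <= window:
                near_pool.append((acc, int(p)))
            else:
                far_pool.append((acc, int(p)))
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    rows = []
    for pool, n_req, flag in ((near_pool, n_near, True), (far_pool, n_far, False)):
        if n_req == 0:
            continue
        if len(pool) < n_req:
            raise ValueError(
                f"cannot place {n_req} {'near' if flag else 'far'} variants; "
                f"only {len(pool)} eligible positions"
            )
        idx = rng.choice(len(pool), size=n_req, replace=False)
        for i in np.sort(idx):
            acc, pos = pool[i]
            ref, alt = rng.choice(aa, size=2, replace=False)
            rows.append(
                {"accession": acc, "position": pos, "ref": ref, "alt": alt,
                 "annotation": "synthetic disease variant", "true_near": flag}
            )
    return pd.DataFrame(
        rows, columns=["accession", "position", "ref", "alt", "annotation",
                       "true_near"]
    )


# ---------------------------------------------------------------------------
# World assembly and file export


def make_world(
    seed: int = 0,
    n_proteins: int = 1000,
    n_datasets: int = 16,
    n_complexes: int = 30,
    complex_size_range: tuple[int, int] = (2, 6),
    n_structures: int = 4,
) -> SyntheticWorld:
    """Assemble a coherent synthetic world.

    Complexes are drawn from endosomal proteins with Gaussian elution peaks
    spread across the usable fraction range; structures are helix bundles
    over pairs of complexed proteins.
    """
    presence, labels = gen_presence_matrix(n_proteins, n_datasets, seed=seed)
    rng = substream(seed, "world")
    endo = sorted(labels[labels == "endosome"].index)
    complexes: list[Complex] = []
    pool = list(endo)
    rng.shuffle(pool)
    lo, hi = complex_size_range
    i = 0
    for k in range(n_complexes):
        size = int(rng.integers(lo, hi + 1))
        if i + size > len(pool):
            break
        members = pool[i: i + size]
        i += size
        peak = float(rng.integers(5, N_FRACTIONS - 4))
        complexes.append(Complex(f"CPX{k:03d}", members, peak))
    structures = []
    for s in range(n_structures):
        if s >= len(complexes) or len(complexes[s].members) < 2:
            break
        a, b = complexes[s].members[:2]
        # chains span 60 Å; a 45 Å z-shift leaves a ~10-residue interface
        structures.append(
            gen_structure(
                [40, 40], accessions=[a, b], seed=seed + s,
                chain_z_shift=45.0, model_id=f"synmodel-{s}",
            )
        )
    return SyntheticWorld(
        seed=seed, proteins=list(presence.index), labels=labels.to_dict(),
        complexes=complexes, structures=structures,
    )


def write_world(world: SyntheticWorld, outdir: str | Path,
                noise_cv: float = 0.1) -> dict[str, str]:
    """Write the world's inputs in the pipeline's on-disk formats.

    TSV cross-link table, per-replicate TSV intensity matrices, mmCIF
    structures, TSV variant table, and a JSON ground-truth sidecar.
    Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    profiles = gen_elution_profiles(
        world.complexes, noise_cv=noise_cv, seed=world.seed
    )
    for rep, df in profiles.items():
        p = outdir / f"elution_rep{rep}.tsv"
        df.to_csv(p, sep="\t")
        paths[f"elution_rep{rep}"] = str(p)

    links_all, variants_all = [], []
    for m in world.structures:
        write_mmcif(m, outdir / f"{m.model_id}.cif")
        paths[m.model_id] = str(outdir / f"{m.model_id}.cif")
        links = gen_crosslinks(m, n_true=20, n_decoy=8, seed=world.seed)
        links.insert(0, "model_id", m.model_id)
        links_all.append(links)
        from endonet.structure import contact_residues

        contacts = contact_residues(m, "A", "B")
        if any(contacts.values()):
            variants = gen_variants(m, contacts, n_near=3, n_far=3,
                                    seed=world.seed)
            variants.insert(0, "model_id", m.model_id)
            variants_all.append(variants)

    if links_all:
        links = pd.concat(links_all, ignore_index=True)
        links.to_csv(outdir / "crosslinks.tsv", sep="\t", index=False)
        paths["crosslinks"] = str(outdir / "crosslinks.tsv")
    if variants_all:
        variants = pd.concat(variants_all, ignore_index=True)
        variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        paths["variants"] = str(outdir / "variants.tsv")

    truth = {
        "seed": world.seed,
        "labels": world.labels,
        "complexes": [
            {"complex_id": c.complex_id, "members": c.members,
             "peak_fraction": c.peak_fraction}
            for c in world.complexes
        ],
        "structures": [m.model_id for m in world.structures],
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths
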