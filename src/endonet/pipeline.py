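"""Pipeline orchestration: run every stage from one config and emit a
summary report mirroring the study-style headline tallies.

The report JSON always contains the full key set (zero counts included):
unique link counts per chemistry, interaction counts per evidence class,
network node/edge/core/community tallies, triangle count, prediction
category tallies, and variant-hit tallies. Runs are deterministic given
config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from endonet import cofrac, meta, network, structure, synthetic, xltable

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds with their standard defaults, plus paths and seed."""

    seed: int = 0
    output_dir: str = "results"
    synthetic: bool = True
    # synthetic world size
    n_proteins: int = 1000
    n_datasets: int = 16
    n_complexes: int = 30
    n_structures: int = 4
    noise_cv: float = 0.1
    # thresholds
    bn_score_min: float = 0.7
    bn_min_replicates: int = 2
    bn_max_complex_size: int = 25
    bn_min_peak_mass_kda: float = 67.0
    xl_score_min: float = 40.0
    spoc_min: float = 0.33
    plddt_min: float = 70.0
    distance_standard: float = 35.0
    distance_link_assisted: float = 30.0
    trimer_interface_min: float = 0.5
    variant_window: int = 2
    rewire_permutations: int = 100
    fp_target: float = 0.10
    # input paths (used when synthetic is False)
    crosslinks_path: str | None = None
    elution_paths: list[str] = field(default_factory=list)
    meta_path: str | None = None
    variants_path: str | None = None

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


EMPTY_REPORT = {
    "meta": {"n_predicted": 0, "n_reference": 0, "n_final_set": 0,
             "threshold": None, "realized_fp_rate": None,
             "partial_auc_combined": None, "recall_reference": None},
    "bn": {"n_candidate_pairs": 0, "n_passing_pairs": 0},
    "xl": {"unique_links": {"DSSO": 0, "DHSO": 0, "DMTMM": 0},
           "n_interactions_xl": 0, "topology_fraction_consistent": None},
    "network": {"n_nodes": 0, "n_edges": 0, "core_nodes": 0, "core_edges": 0,
                "n_communities": 0, "mean_shortest_path": None,
                "powerlaw_r2": None, "n_3cliques": 0},
    "structures": {"n_models": 0, "n_links_evaluated": 0,
                   "fraction_within": None, "fraction_within_inter": None,
                   "categories": {"supported": 0, "unstructured-only": 0,
                                  "violated": 0, "low-confidence": 0,
                                  "unscored": 0}},
    "variants": {"n_variants": 0, "n_near_interface": 0},
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the report dict (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = json.loads(json.dumps(EMPTY_REPORT))  # deep copy
    report["config"] = asdict(config)

    if not config.synthetic:
        raise NotImplementedError(
            "file-based runs wire real tables through the same stage "
            "functions; supply --synthetic for the self-contained run"
        )

    world = synthetic.make_world(
        seed=config.seed, n_proteins=config.n_proteins,
        n_datasets=config.n_datasets, n_complexes=config.n_complexes,
        n_structures=config.n_structures,
    )

    # ---- meta-analysis ----------------------------------------------------
    try:
        presence, labels = synthetic.gen_presence_matrix(
            config.n_proteins, config.n_datasets, seed=config.seed
        )
        evidence = synthetic.gen_meta_evidence(presence, labels,
                                               seed=config.seed)
        combined = meta.combine_scores(evidence)
        roc = meta.metric_roc(combined, evidence["is_reference"],
                              fp_max=config.fp_target)
        calls, threshold = meta.call_endosomal(
            combined, evidence["is_reference"], fp_target=config.fp_target,
            exclusion=evidence["is_mito_excludable"],
        )
        ref_recall = float(
            calls.loc[calls["is_reference"], "predicted_endosomal"].mean()
        )
        report["meta"] = {
            "n_predicted": int(calls["predicted_endosomal"].sum()),
            "n_reference": int(calls["is_reference"].sum()),
            "n_final_set": int(calls["in_final_set"].sum()),
            "threshold": threshold,
            "realized_fp_rate": meta.realized_fp_rate(calls),
            "partial_auc_combined": roc.partial_auc,
            "recall_reference": ref_recall,
        }
        calls.to_csv(outdir / "meta_calls.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001 - stage failures must name the stage
        raise RuntimeError(f"stage meta_proteome failed: {exc}") from exc

    # ---- co-fractionation -------------------------------------------------
    try:
        profiles = synthetic.gen_elution_profiles(
            world.complexes, noise_cv=config.noise_cv, seed=config.seed
        )
        pairs = []
        sizes, peaks = {}, {}
        for cx in world.complexes:
            for i, a in enumerate(cx.members):
                for b in cx.members[i + 1:]:
                    pairs.append(tuple(sorted((a, b))))
                    sizes[pairs[-1]] = len(cx.members)
                    peaks[pairs[-1]] = cx.peak_fraction
        scores = cofrac.scores_from_replicates(profiles, pairs)
        wide = scores.pivot_table(
            index=["accession_a", "accession_b"], columns="replicate",
            values="score",
        )
        candidates = pd.DataFrame(
            {
                "accession_a": [p[0] for p in wide.index],
                "accession_b": [p[1] for p in wide.index],
                "scores": wide.values.tolist(),
                "complex_size": [sizes[p] for p in wide.index],
                # marker calibration for the synthetic gel: apparent mass
                # decreases log-linearly from 3 MDa (fraction 1) to 20 kDa
                "peak_mass_kda": [
                    float(10 ** np.interp(peaks[p], [1, 48],
                                          [np.log10(3000), np.log10(20)]))
                    for p in wide.index
                ],
            }
        )
        filtered = cofrac.filter_bn_candidates(
            candidates, score_min=config.bn_score_min,
            min_replicates=config.bn_min_replicates,
            max_complex_size=config.bn_max_complex_size,
            min_peak_mass_kda=config.bn_min_peak_mass_kda,
        )
        passing = filtered[filtered["passes_filters"]]
        report["bn"] = {
            "n_candidate_pairs": len(filtered),
            "n_passing_pairs": len(passing),
        }
        filtered.drop(columns=["scores"]).to_csv(
            outdir / "bn_pairs.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage cofractionation failed: {exc}") from exc

    # ---- cross-links ------------------------------------------------------
    try:
        links_raw = []
        for m in world.structures:
            lk = synthetic.gen_crosslinks(m, n_true=20, n_decoy=8,
                                          seed=config.seed)
            links_raw.append(lk)
        links_raw = (
            pd.concat(links_raw, ignore_index=True)
            if links_raw else pd.DataFrame(
                columns=["accession_a", "pos_a", "accession_b", "pos_b",
                         "chemistry", "score", "replicate"]
            )
        )
        unique_links, dedup_report = xltable.dedup_and_filter(
            links_raw, score_min=config.xl_score_min
        )
        per_chem = unique_links.groupby("chemistry").size().to_dict()
        xl_pairs = xltable.collapse_to_pairs(unique_links)
        hetero = xl_pairs[~xl_pairs["is_self"]]
        # soluble-protein topology: one cytosolic segment per protein
        annotations = pd.DataFrame(
            [
                {"accession": acc, "start": 1, "end": 10_000,
                 "compartment": "cytosolic"}
                for acc in pd.unique(
                    unique_links[["accession_a", "accession_b"]].to_numpy().ravel()
                )
            ]
        )
        if len(unique_links):
            _, topo_report = xltable.topology_check(unique_links, annotations)
            topo_frac = topo_report["fraction_consistent"]
        else:
            topo_frac = None
        report["xl"] = {
            "unique_links": {
                "DSSO": int(per_chem.get("DSSO", 0)),
                "DHSO": int(per_chem.get("DHSO", 0)),
                "DMTMM": int(per_chem.get("DMTMM", 0)),
            },
            "n_interactions_xl": len(hetero),
            "topology_fraction_consistent": topo_frac,
        }
        unique_links.to_csv(outdir / "unique_links.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage crosslink_table failed: {exc}") from exc

    # ---- network ----------------------------------------------------------
    try:
        bn_edges = passing.rename(columns={"bn_replicates_passing": "bn_replicates_passing"})
        xl_edges = hetero
        g = network.build_network(xl_edges, bn_edges)
        endo = world.endosomal
        g_endo = network.endosome_center_filter(
            g, endo, nuclear={p for p, c in world.labels.items()
                              if c == "nucleus"},
        )
        core = network.core_component(g_endo)
        stats = network.network_stats(g_endo)
        communities = network.detect_communities(core) if core.number_of_nodes() else []
        cliques = network.enumerate_3cliques(g_endo)
        report["network"] = {
            "n_nodes": stats.get("n_nodes", 0),
            "n_edges": stats.get("n_edges", 0),
            "core_nodes": core.number_of_nodes(),
            "core_edges": core.number_of_edges(),
            "n_communities": len(communities),
            "mean_shortest_path": stats.get("mean_shortest_path"),
            "powerlaw_r2": stats.get("powerlaw_r2"),
            "n_3cliques": len(cliques),
        }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage interactome failed: {exc}") from exc

    # ---- structures -------------------------------------------------------
    try:
        categories = dict.fromkeys(
            ("supported", "unstructured-only", "violated", "low-confidence",
             "unscored"), 0,
        )
        n_links_eval = 0
        within_all, inter_all = [], []
        n_near = 0
        n_variants = 0
        for m in world.structures:
            lk = synthetic.gen_crosslinks(m, n_true=20, n_decoy=8,
                                          seed=config.seed)
            evals, summary = structure.evaluate_crosslinks(
                m, lk, plddt_min=config.plddt_min
            )
            n_links_eval += summary["n_links"]
            if summary["fraction_within"] is not None:
                within_all.append(
                    (summary["n_within"],
                     summary["n_within"] + summary["n_exceeded"])
                )
            if summary["fraction_within_inter"] is not None:
                inter = evals[~evals["is_intra"]]
                measured = inter[inter["status"].isin(["within", "exceeded"])]
                inter_all.append(
                    (int((measured["status"] == "within").sum()), len(measured))
                )
            cat = structure.classify_prediction(
                spoc=0.8, evaluations=evals, spoc_min=config.spoc_min
            )
            categories[cat] += 1
            contacts = structure.contact_residues(m, "A", "B")
            if any(contacts.values()):
                variants = synthetic.gen_variants(
                    m, contacts, n_near=3, n_far=3, seed=config.seed
                )
                hits = structure.variant_interface_scan(
                    variants, contacts, window=config.variant_window
                )
                n_variants += len(hits)
                n_near += int(hits["near_interface"].sum())

        def ratio(acc: list[tuple[int, int]]) -> float | None:
            n = sum(t for _, t in acc)
            return sum(w for w, _ in acc) / n if n else None

        report["structures"] = {
            "n_models": len(world.structures),
            "n_links_evaluated": n_links_eval,
            "fraction_within": ratio(within_all),
            "fraction_within_inter": ratio(inter_all),
            "categories": categories,
        }
        report["variants"] = {
            "n_variants": n_variants,
            "n_near_interface": n_near,
        }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage structure_check failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
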