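"""End-to-end orchestration: annotate -> network -> featurize -> evaluate.

This module wires the stages together for whole chains and exposes the
standard experiments: chain-level cross-validation, the patch-size sweep
over both PSSM encodings, the leave-one-feature-out ablation, and the
top-k case study that ranks surface residues of a single labeled complex
by raw or weighted-average betweenness centrality (or interface
propensity).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import classify, features, network, surface
from .classify import ResidueRecord, cross_validate
from .features import (
    DEFAULT_PATCH_SIZE,
    DEFAULT_WEIGHT_SCHEME,
    PssmProfile,
    build_surface_patch,
    c_pssm,
    interface_propensity_table,
    rw_pssm,
    scale_pssm,
    weighted_scalar_feature,
)
from .metrics import top_k_ranking_eval
from .structure import Residue

__all__ = [
    "RunConfig",
    "ChainFeatures",
    "featurize_chain",
    "records_from_chains",
    "run_cv",
    "run_patch_size_sweep",
    "run_ablation",
    "run_case_study",
]


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one run; embedded in every output."""

    L: int = DEFAULT_PATCH_SIZE
    weight_scheme: str = DEFAULT_WEIGHT_SCHEME
    surface_threshold: float = surface.SURFACE_RSA_THRESHOLD
    binding_cutoff: float = surface.BINDING_CUTOFF
    contact_cutoff: float = network.CONTACT_CUTOFF
    n_sphere_points: int = surface.DEFAULT_N_SPHERE_POINTS
    pseudocount: float = 1.0
    svm_c: float = classify.DEFAULT_C
    svm_gamma: str | float = classify.DEFAULT_GAMMA
    threshold: float = 0.0
    encoding: str = "rw_pssm"      # rw_pssm | c_pssm
    feature_set: str = "full"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ChainFeatures:
    chain_id: str
    records: list[ResidueRecord]
    annotations: list[surface.SurfaceAnnotation]
    betweenness: dict
    patches: dict
    c_pssm_matrix: np.ndarray | None = None


def featurize_chain(
    protein_residues: list[Residue],
    dna_residues: list[Residue] | None,
    raw_profile: PssmProfile,
    config: RunConfig = RunConfig(),
    with_c_pssm: bool = False,
) -> ChainFeatures:
    """Annotate one chain and build one record per surface residue.

    ASA and the surface flag are computed on the isolated protein chain;
    binding labels come from the DNA coordinates when present (all
    surface residues are nonbinding otherwise); the contact graph and
    patches use only this chain's residues.
    """
    annotations = surface.annotate_chain(
        protein_residues,
        dna_residues,
        n_sphere_points=config.n_sphere_points,
        surface_threshold=config.surface_threshold,
        binding_cutoff=config.binding_cutoff,
    )
    contact = network.build_contact_graph(protein_residues, config.contact_cutoff)
    bc = network.betweenness_centrality(contact)
    profile = raw_profile if raw_profile.keys else raw_profile.attach(protein_residues)
    profile = scale_pssm(profile)

    surf_anns = [a for a in annotations if a.is_surface]
    surf_residues = [a.residue for a in surf_anns]
    records, patches = [], {}
    c_rows = []
    sc_by_key = {a.key: a.asa.sc_asa for a in surf_anns}
    for ann in surf_anns:
        patch = build_surface_patch(
            ann.residue, surf_residues, L=config.L, scheme=config.weight_scheme
        )
        patches[ann.key] = patch
        records.append(
            ResidueRecord(
                chain_id=ann.key[0],
                key=ann.key,
                name=ann.residue.parent_name,
                label=ann.binding_label == "binding",
                rw_pssm=rw_pssm(patch, profile),
                wbc=weighted_scalar_feature(patch, bc),
                sc_asa=sc_by_key[ann.key],
                patch_member_names=patch.member_names,
                patch_weights=patch.weights,
            )
        )
        if with_c_pssm:
            c_rows.append(c_pssm(patch, profile, config.L))
    return ChainFeatures(
        chain_id=protein_residues[0].chain_id if protein_residues else "?",
        records=records,
        annotations=annotations,
        betweenness=bc,
        patches=patches,
        c_pssm_matrix=np.array(c_rows) if with_c_pssm else None,
    )


def records_from_chains(chains, config: RunConfig = RunConfig()) -> list[ResidueRecord]:
    """Featurize a list of ``ChainFixture``-like objects (protein_residues,
    dna_residues, profile attributes) into one record list."""
    records = []
    for chain in chains:
        feats = featurize_chain(
            chain.protein_residues, chain.dna_residues, chain.profile, config
        )
        records.extend(feats.records)
    return records


def run_cv(records, config: RunConfig = RunConfig(), folds=None) -> classify.CvResult:
    return cross_validate(
        records,
        n_folds=5,
        seed=config.seed,
        C=config.svm_c,
        gamma=config.svm_gamma,
        feature_set=config.feature_set,
        threshold=config.threshold,
        pseudocount=config.pseudocount,
        folds=folds,
    )


def _cv_with_encoding(chains, config: RunConfig, encoding: str) -> float:
    """Mean CV PR-AUC for one patch size and encoding.

    For the concatenated encoding the PSSM block is the 20 L member rows
    instead of the 40 reduced values; WIP, WBC and ScASA ride along
    unchanged so the comparison isolates the PSSM representation.
    """
    rng = np.random.default_rng(config.seed)
    all_records = []
    for chain in chains:
        feats = featurize_chain(
            chain.protein_residues, chain.dna_residues, chain.profile,
            config, with_c_pssm=(encoding == "c_pssm"),
        )
        recs = feats.records
        if encoding == "c_pssm":
            for rec, row in zip(recs, feats.c_pssm_matrix):
                rec.rw_pssm = row  # PSSM block replaced by the concatenation
        all_records.extend(recs)
    result = cross_validate(
        all_records, n_folds=5, seed=rng,
        C=config.svm_c, gamma=config.svm_gamma,
        threshold=config.threshold, pseudocount=config.pseudocount,
    )
    return result.mean_metric("pr_auc")


def run_patch_size_sweep(
    chains, sizes, encodings=("rw_pssm", "c_pssm"), config: RunConfig = RunConfig()
) -> pd.DataFrame:
    """PR-AUC per (patch size, encoding) via 5-fold chain-level CV."""
    from dataclasses import replace

    rows = []
    for L in sizes:
        for encoding in encodings:
            auc = _cv_with_encoding(chains, replace(config, L=L), encoding)
            dim = (40 if encoding == "rw_pssm" else 20 * L) + 3
            rows.append(
                {"L": L, "encoding": encoding, "pr_auc": auc, "feature_dim": dim}
            )
    return pd.DataFrame(rows)


def run_ablation(
    chains,
    feature_sets=tuple(features.FEATURE_SETS),
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Leave-one-feature-out metric table on shared folds and seeds."""
    from dataclasses import replace

    records = records_from_chains(chains, config)
    fold_rng = np.random.default_rng(config.seed)
    folds = classify.split_chains([r.chain_id for r in records], 5, fold_rng)
    fold_hash = hash(tuple(tuple(f) for f in folds)) & 0xFFFFFFFF
    rows = []
    for fs in feature_sets:
        result = run_cv(records, replace(config, feature_set=fs), folds=folds)
        mean = result.table().iloc[-1]
        rows.append(
            {
                "feature_set": fs,
                "recall": mean["recall"],
                "precision": mean["precision"],
                "f1": mean["f1"],
                "pr_auc": mean["pr_auc"],
                "fold_hash": fold_hash,
            }
        )
    return pd.DataFrame(rows)


def run_case_study(
    protein_residues: list[Residue],
    dna_residues: list[Residue],
    config: RunConfig = RunConfig(),
    k: int | None = None,
    rankers: tuple[str, ...] = ("bc", "wbc", "ip", "wip"),
    ip_table=None,
) -> dict:
    """Rank surface residues of one labeled complex and score the top k.

    Implements the single-structure experiment: label binding residues
    by the 4.5 A rule, rank surface residues by raw betweenness (bc),
    weighted-average betweenness (wbc), interface propensity (ip) or
    weighted-average propensity (wip), take the k top-ranked residues
    (k defaults to the number of true binders, making recall equal
    precision) and report recall/precision per ranker.

    ``ip`` rankers need a propensity table; when none is supplied it is
    derived from this chain's own labels (self-propensity; fine for
    illustration, not for benchmarking).
    """
    annotations = surface.annotate_chain(
        protein_residues, dna_residues,
        n_sphere_points=config.n_sphere_points,
        surface_threshold=config.surface_threshold,
        binding_cutoff=config.binding_cutoff,
    )
    surf_anns = [a for a in annotations if a.is_surface]
    surf_residues = [a.residue for a in surf_anns]
    true_binding = {a.key for a in surf_anns if a.binding_label == "binding"}
    if k is None:
        k = len(true_binding)
    contact = network.build_contact_graph(protein_residues, config.contact_cutoff)
    bc = network.betweenness_centrality(contact)

    needs_ip = any(r in rankers for r in ("ip", "wip"))
    if needs_ip and ip_table is None:
        ip_table = interface_propensity_table(
            [(a.residue.parent_name, a.binding_label) for a in surf_anns],
            pseudocount=config.pseudocount,
        )

    out = {
        "n_surface": len(surf_anns),
        "n_binding": len(true_binding),
        "binding_residues": [
            a.residue.label()
            for a in sorted(surf_anns, key=lambda a: (a.key[1], a.key[2]))
            if a.binding_label == "binding"
        ],
        "k": k,
        "rankings": {},
    }
    for ranker in rankers:
        if ranker == "bc":
            values = {a.key: bc[a.key] for a in surf_anns}
        elif ranker == "ip":
            values = {a.key: ip_table.of(a.residue.parent_name) for a in surf_anns}
        else:
            base = (
                bc
                if ranker == "wbc"
                else {a.key: ip_table.of(a.residue.parent_name) for a in surf_anns}
            )
            values = {}
            for ann in surf_anns:
                patch = build_surface_patch(
                    ann.residue, surf_residues, L=config.L, scheme=config.weight_scheme
                )
                values[ann.key] = weighted_scalar_feature(patch, base)
        recall, precision, predicted = top_k_ranking_eval(values, true_binding, k)
        out["rankings"][ranker] = {
            "recall": recall,
            "precision": precision,
            "predicted": predicted,
        }
    return out
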