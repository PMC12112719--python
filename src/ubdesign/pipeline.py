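"""End-to-end design-funnel driver.

Chains the stages curate -> train -> generate -> filter -> triage ->
energetics -> maturate from one declarative config, writing a TSV report
per stage plus a final funnel summary.  With no input library configured
the synthetic fixture library is used, which makes a fully offline,
seed-deterministic desk-scale run possible: identical config + seed give
byte-identical reports.

Stage artifacts (FASTA libraries, VAE checkpoint + history, filter
reports, pose manifests, energy tables, mutant lists) are written under
the configured output directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import seq_data, seq_filters, vae
from .energetics import EnergeticsConfig, band_candidates, binding_dg, hotspots
from .fixtures import (
    FixtureConfig,
    make_decomposition,
    make_energy_frames,
    make_library,
    make_plddt_tracks,
    make_pose_deck,
)
from .maturation import (
    MaturationConfig,
    apply_mutant,
    cluster_pool,
    consensus_mutants,
    diff_mutations,
    enumerate_singles,
)
from .pose_triage import TriageConfig, InterfacePatch, funnel_select, greedy_diverse_top, interface_filter
from .seq_filters import FilterConfig

ALL_STAGES = ("curate", "train", "generate", "filter", "triage", "energetics", "maturate")

#: scaled-down per-target class counts used by the desk-scale fixture run
DESK_SCALE_MARGINALS = {
    "HER2": {"SB": 12, "MB": 10, "WB": 3},
    "FINC_EDB": {"SB": 6, "MB": 5, "WB": 3},
    "Others": {"SB": 21, "MB": 34, "WB": 26},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative run description; defaults are desk-scale fixture sizes."""

    seed: int = 0
    outdir: str = "pipeline_out"
    stages: tuple[str, ...] = ALL_STAGES
    library_fasta: str | None = None  # None -> synthetic fixture library
    fixture_library_size: int = 120
    fixture_monomer_count: int = 52
    class_marginals: dict[str, dict[str, int]] = field(
        default_factory=lambda: {t: dict(c) for t, c in DESK_SCALE_MARGINALS.items()}
    )
    # VAE (desk scale; library-scale defaults live in vae.VAEConfig)
    vae_units: int = 64
    vae_fc_units: int = 32
    vae_latent_dim: int = 16
    vae_max_epochs: int = 120
    vae_patience: int = 20
    vae_batch_size: int = 32
    n_generated: int = 40
    temperature: float = 0.8
    # filtering
    identity_min: float = 0.75
    identity_max: float = 0.90
    length_min: int = 72
    length_max: int = 84
    plddt_floor: float = 50.0
    # triage
    n_candidates: int = 6
    pose_deck_size: int = 40
    contact_cutoff: float = 10.0
    diversity_rmsd: float = 2.0
    max_kept_poses: int = 50
    docking_top_k: int = 50
    refine_top_k: int = 10
    # energetics / maturation
    hotspot_threshold: float = -2.0
    n_energy_frames: int = 200
    maturation_pool_size: int = 40
    cluster_identity: float = 0.975
    max_consensus_order: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in order; returns per-stage summaries.

    Each stage writes a TSV report; a stage failure raises `StageError`
    naming the stage.  Disabled stages are skipped and downstream stages
    consume the most recent upstream artifact.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}
    funnel_rows: list[dict[str, Any]] = []

    state: dict[str, Any] = {}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        try:
            n_in, n_out = _STAGE_FUNCS[stage](cfg, out, state, summary)
        except Exception as exc:  # noqa: BLE001 - report which stage failed
            raise StageError(stage, exc) from exc
        funnel_rows.append({"stage": stage, "n_in": n_in, "n_out": n_out})
    _write_tsv(pd.DataFrame(funnel_rows), out / "funnel_summary.tsv")
    summary["funnel"] = funnel_rows
    return summary


# -- individual stages ------------------------------------------------------


def _stage_curate(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    if cfg.library_fasta:
        library = seq_data.read_fasta(cfg.library_fasta)
    else:
        library = make_library(
            FixtureConfig(
                seed=cfg.seed,
                library_size=cfg.fixture_library_size,
                monomer_count=cfg.fixture_monomer_count,
                class_marginals=cfg.class_marginals,
            )
        )
    ds_cfg = seq_data.DatasetConfig()
    monomers = [m for r in library for m in seq_data.split_dimer(r, ds_cfg)]
    curated = seq_data.deduplicate(monomers, ds_cfg)
    seq_data.write_fasta(curated, out / "curated.fasta")
    report = pd.DataFrame(
        [
            {
                "records_in": len(library),
                "monomers_after_split": len(monomers),
                "kept_after_dedup": len(curated),
                "dedup_identity": ds_cfg.dedup_identity,
                "seed": cfg.seed,
            }
        ]
    )
    _write_tsv(report, out / "curate_report.tsv")
    state["curated"] = curated
    summary["curate"] = report.iloc[0].to_dict()
    return len(library), len(curated)


def _stage_train(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    curated = state.get("curated") or seq_data.read_fasta(out / "curated.fasta")
    max_len = max(len(r) for r in curated)
    spec = vae.EncodingSpec(max_len=max_len + 4)
    vcfg = vae.VAEConfig(
        encoder_lstm_units=cfg.vae_units,
        encoder_fc_units=cfg.vae_fc_units,
        latent_dim=cfg.vae_latent_dim,
        decoder_state_units=cfg.vae_units,
        decoder_lstm_units=cfg.vae_units,
        max_epochs=cfg.vae_max_epochs,
        early_stop_patience=cfg.vae_patience,
        batch_size=cfg.vae_batch_size,
        seed=cfg.seed,
    )
    model = vae.train(curated, vcfg, spec)
    model.save(out / "vae_checkpoint.zip")
    vae.write_history_csv(model, out / "vae_history.csv")
    _write_tsv(model.history, out / "train_report.tsv")
    state["model"] = model
    summary["train"] = {
        "epochs": len(model.history),
        "final_train_recon": float(model.history["train_recon"].iloc[-1]),
    }
    return len(curated), len(model.history)


def _stage_generate(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    model = state.get("model") or vae.GeneratorModel.load(out / "vae_checkpoint.zip")
    gcfg = vae.GenerationConfig(
        n_sequences=cfg.n_generated, temperature=cfg.temperature, seed=cfg.seed + 10
    )
    seqs = [s for s in vae.generate(model, gcfg) if s]
    records = [
        seq_data.SequenceRecord(id=f"gen_{i + 1:04d}", sequence=s)
        for i, s in enumerate(seqs)
    ]
    seq_data.write_fasta(records, out / "generated.fasta")
    report = pd.DataFrame(
        [
            {
                "requested": cfg.n_generated,
                "non_empty": len(records),
                "temperature": cfg.temperature,
                "seed": gcfg.seed,
            }
        ]
    )
    _write_tsv(report, out / "generate_report.tsv")
    state["generated"] = records
    summary["generate"] = report.iloc[0].to_dict()
    return cfg.n_generated, len(records)


def _stage_filter(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    records = state.get("generated") or seq_data.read_fasta(out / "generated.fasta")
    fcfg = FilterConfig(
        identity_min=cfg.identity_min,
        identity_max=cfg.identity_max,
        length_min=cfg.length_min,
        length_max=cfg.length_max,
        plddt_floor=cfg.plddt_floor,
    )
    kept, report = seq_filters.filter_generated(
        [(r.id, r.sequence) for r in records], fcfg
    )
    # synthetic per-model confidence tracks stand in for predicted-structure
    # quality of the kept designs
    n_fail = min(len(kept) // 10, 11)
    tracks, _ = make_plddt_tracks(
        FixtureConfig(
            seed=cfg.seed + 20,
            plddt_model_count=max(len(kept), 1),
            plddt_fail_count=n_fail,
        )
    )
    tracks = tracks[: len(kept)]
    surviving_models, mean_plddt = (
        seq_filters.plddt_filter(tracks, fcfg.plddt_floor) if kept else ([], 0.0)
    )
    pass_ids = {m.id for m in surviving_models}
    final = [
        rec for rec, track in zip(kept, tracks) if track.id in pass_ids
    ]
    pass_by_design = {
        rec[0]: track.id in pass_ids for rec, track in zip(kept, tracks)
    }
    report["plddt_pass"] = report["id"].map(lambda i: pass_by_design.get(i, False))
    _write_tsv(report, out / "filter_report.tsv")
    final_records = [
        seq_data.SequenceRecord(id=rid, sequence=s) for rid, s in final
    ]
    seq_data.write_fasta(final_records, out / "filtered.fasta")
    state["filtered"] = final_records
    summary["filter"] = {
        "n_in": len(records),
        "identity_length_pass": len(kept),
        "plddt_pass": len(final),
        "mean_plddt": mean_plddt,
    }
    return len(records), len(final)


def _stage_triage(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    if "filtered" in state:
        candidates = state["filtered"]
    elif "generated" in state:
        candidates = state["generated"]
    else:
        candidates = seq_data.read_fasta(out / "filtered.fasta")
    candidates = candidates[: cfg.n_candidates]
    if not candidates:
        raise ValueError("no candidates reached the triage stage")
    tcfg = TriageConfig(
        contact_cutoff=cfg.contact_cutoff,
        diversity_rmsd=cfg.diversity_rmsd,
        max_kept_poses=cfg.max_kept_poses,
        docking_top_k=cfg.docking_top_k,
        refine_top_k=cfg.refine_top_k,
    )
    rec_patch = InterfacePatch("receptor", frozenset(range(5, 16)))
    lig_patch = InterfacePatch("ligand", frozenset(range(1, 13)))
    rows = []
    docking_scores: dict[str, float] = {}
    refine_scores: dict[str, float] = {}
    for i, cand in enumerate(candidates):
        deck, _ = make_pose_deck(
            FixtureConfig(seed=cfg.seed + 30 + i, pose_deck_size=cfg.pose_deck_size)
        )
        in_contact = interface_filter(deck, rec_patch, lig_patch, tcfg)
        kept = greedy_diverse_top(in_contact, tcfg)
        from .pose_triage import mean_top_k

        docking_scores[cand.id] = mean_top_k([p.score for p in kept], tcfg.docking_top_k)
        refine_scores[cand.id] = mean_top_k([p.score for p in kept], tcfg.refine_top_k)
        rows.append(
            {
                "candidate": cand.id,
                "poses": len(deck),
                "in_contact": len(in_contact),
                "diverse_kept": len(kept),
                "mean_top_docking": docking_scores[cand.id],
                "mean_top_refine": refine_scores[cand.id],
            }
        )
    docking_pass = funnel_select(docking_scores)
    refine_pass = funnel_select({c: refine_scores[c] for c in docking_pass})
    for row in rows:
        row["docking_pass"] = row["candidate"] in docking_pass
        row["refine_pass"] = row["candidate"] in refine_pass
    report = pd.DataFrame(rows)
    _write_tsv(report, out / "triage_report.tsv")
    survivors = [c for c in candidates if c.id in refine_pass]
    state["triaged"] = survivors
    summary["triage"] = {
        "candidates": len(candidates),
        "docking_pass": len(docking_pass),
        "refine_pass": len(refine_pass),
    }
    return len(candidates), len(survivors)


def _stage_energetics(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    if "triaged" in state:
        survivors = state["triaged"]
    else:
        survivors = seq_data.read_fasta(out / "filtered.fasta")
    if not survivors:
        raise ValueError("no candidates reached the energetics stage")
    rng = np.random.default_rng(cfg.seed + 40)
    ecfg = EnergeticsConfig(hotspot_threshold=cfg.hotspot_threshold)
    dgs: dict[str, float] = {}
    rows = []
    for i, cand in enumerate(survivors):
        frames = make_energy_frames(
            n_frames=cfg.n_energy_frames,
            mean_dg=float(rng.uniform(-40.0, -15.0)),
            sigma=3.0,
            seed=cfg.seed + 50 + i,
        )
        dg, se = binding_dg(frames)
        dgs[cand.id] = dg
        rows.append({"candidate": cand.id, "dG": dg, "dG_se": se})
    bands = (
        band_candidates(dgs, ecfg)
        if len(dgs) >= 3
        else {c: "NA" for c in dgs}
    )
    for row in rows:
        row["band"] = bands[row["candidate"]]
    table, _, _ = make_decomposition(FixtureConfig(seed=cfg.seed + 60))
    hot = hotspots(table, ecfg)
    best = min(dgs, key=lambda c: (dgs[c], c))
    report = pd.DataFrame(rows)
    _write_tsv(report, out / "energetics_report.tsv")
    hot_df = pd.DataFrame(
        [{"chain": c, "resid": r} for c, r in sorted(hot)]
    )
    _write_tsv(hot_df, out / "hotspots.tsv")
    state["dgs"] = dgs
    state["best_candidate"] = next(c for c in survivors if c.id == best)
    state["decomposition"] = table
    summary["energetics"] = {"n_candidates": len(dgs), "best": best, "best_dG": dgs[best]}
    return len(survivors), len(dgs)


def _stage_maturate(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    parent = state.get("best_candidate")
    if parent is None:
        candidates = seq_data.read_fasta(out / "filtered.fasta")
        if not candidates:
            raise ValueError("no parent hit available for maturation")
        parent = candidates[0]
    mcfg = MaturationConfig(
        cluster_identity=cfg.cluster_identity,
        n_generated_per_hit=cfg.maturation_pool_size,
        max_consensus_order=cfg.max_consensus_order,
    )
    rng = np.random.default_rng(cfg.seed + 70)
    pseq = parent.sequence
    from .constants import AA_ALPHABET

    pool = []
    for _ in range(mcfg.n_generated_per_hit):
        seq = list(pseq)
        for pos in rng.choice(len(pseq), size=int(rng.integers(1, 4)), replace=False):
            options = [a for a in AA_ALPHABET if a != seq[pos]]
            seq[pos] = options[int(rng.integers(len(options)))]
        pool.append("".join(seq))
    clusters, centroids = cluster_pool(pool, mcfg)
    specs = [diff_mutations(pseq, pool[c], parent.id) for c in centroids]
    singles = enumerate_singles([s for s in specs if s.order > 0])
    # synthetic per-single ΔΔG stand-in for the MD-based scoring
    scored = {
        str(s): round(float(rng.normal(-0.5, 1.5)), 3) for s in singles
    }
    consensus = (
        consensus_mutants(
            [(s, scored[str(s)]) for s in singles], mcfg, parent.id
        )
        if len(singles) >= 2
        else []
    )
    rows = [
        {"mutant": m, "ddG": g, "kind": "single"} for m, g in scored.items()
    ] + [
        {"mutant": str(m), "ddG": float("nan"), "kind": "consensus"}
        for m in consensus
    ]
    report = pd.DataFrame(rows, columns=["mutant", "ddG", "kind"])
    _write_tsv(report, out / "maturation_report.tsv")
    mutants = [
        seq_data.SequenceRecord(id=f"{parent.id}|{m}", sequence=apply_mutant(pseq, m))
        for m in consensus
    ]
    if mutants:
        seq_data.write_fasta(mutants, out / "consensus_mutants.fasta")
    summary["maturate"] = {
        "pool": len(pool),
        "clusters": len(clusters),
        "singles": len(singles),
        "consensus": len(consensus),
    }
    return len(pool), len(singles) + len(consensus)


_STAGE_FUNCS = {
    "curate": _stage_curate,
    "train": _stage_train,
    "generate": _stage_generate,
    "filter": _stage_filter,
    "triage": _stage_triage,
    "energetics": _stage_energetics,
    "maturate": _stage_maturate,
}
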