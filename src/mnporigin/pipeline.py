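"""End-to-end workflow orchestration.

Stage order: simulate → profile → pretrain → fine-tune → two-step clean →
retrain on the cleaned data → evaluate → interpret.  The step-2
neighborhood filter always uses embeddings from the model retrained on
step-1-cleaned data, and every stage derives its seed deterministically
from the global seed.  Run directories are content-addressed by config
hash; an existing directory is never silently overwritten.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chem_io import LabeledDataset, save_dataset
from .classify_eval import confusion, table_report, train_head
from .cleaning import (
    CleaningReport,
    apply_cleaning,
    auto_radius,
    cross_prediction_screen,
    model_trainer,
    neighborhood_filter,
)
from .descriptors import (
    cluster_fingerprints,
    cluster_sets,
    morgan_fp_table,
    overlap_counts,
    physchem_profile,
    scaffold_sets,
    top_scaffolds,
)
from .encoder import EncoderConfig, extract_embeddings, finetune, pretrain
from .interpret import MCTSConfig, aggregate_rationales, mcts_rationales
from .synthetic import GrammarParams, SyntheticSpec, generate_dataset, inject_label_noise

logger = logging.getLogger(__name__)


def _stage_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31)


@dataclass
class PipelineConfig:
    """Declarative configuration for one full run (desk scale by default)."""

    n_per_class: dict[int, int] = field(default_factory=lambda: {0: 200, 1: 100, 2: 100})
    test_n_per_class: dict[int, int] = field(default_factory=lambda: {0: 60, 1: 30, 2: 30})
    noise_rate: float = 0.08
    seed: int = 0
    encoder: EncoderConfig = field(default_factory=lambda: EncoderConfig(hidden_dim=64))
    cycles: int = 10
    subset_fraction: float = 0.5
    radius: float | str = "auto"
    radius_quantile: float = 0.01
    coverage: str = "strict"
    head: str = "gbt"
    mcts: MCTSConfig = field(default_factory=lambda: MCTSConfig(rollouts=15, min_atoms=6, max_atoms=16))
    rationales_per_class: int = 2
    run_profile: bool = True
    run_cleaning: bool = True
    run_interpret: bool = True
    out_dir: str = "runs"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the workflow; returns the artifact directory."""
    run_dir = Path(cfg.out_dir) / f"run_{cfg.config_hash()}"
    if run_dir.exists():
        raise FileExistsError(
            f"{run_dir} already exists; runs are content-addressed and never overwritten"
        )
    run_dir.mkdir(parents=True)
    log: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "stages": {},
    }
    stage_t0 = time.time()

    def done(stage: str):
        log["stages"][stage] = round(time.time() - stage_t0, 3)
        (run_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    current = "simulate"
    try:
        # --- simulate -----------------------------------------------------
        spec = SyntheticSpec(n_per_class=cfg.n_per_class, noise_rate=cfg.noise_rate,
                             seed=_stage_seed(cfg.seed, 1))
        clean_truth = generate_dataset(spec)
        noisy, planted = inject_label_noise(clean_truth, cfg.noise_rate,
                                            _stage_seed(cfg.seed, 2))
        test_spec = SyntheticSpec(n_per_class=cfg.test_n_per_class,
                                  seed=_stage_seed(cfg.seed, 3))
        test_ds = generate_dataset(test_spec)
        save_dataset(noisy, run_dir / "train.csv")
        save_dataset(test_ds, run_dir / "test.csv")
        pd.DataFrame(
            {
                "id": clean_truth.ids,
                "true_label": [r.label for r in clean_truth],
                "planted_flag": [int(cid in planted) for cid in clean_truth.ids],
            }
        ).to_csv(run_dir / "truth.csv", index=False)
        done("simulate")

        # --- profile ------------------------------------------------------
        if cfg.run_profile:
            current = "profile"
            physchem_profile(noisy).to_csv(run_dir / "descriptors.csv")
            scafs = top_scaffolds(noisy)
            (run_dir / "top_scaffolds.json").write_text(
                json.dumps({str(k): v for k, v in scafs.items()}, indent=2)
            )
            fps = morgan_fp_table(noisy)
            clusters = cluster_fingerprints(fps, k="auto",
                                            seed=_stage_seed(cfg.seed, 4))
            venn = {
                "scaffolds": overlap_counts(scaffold_sets(noisy)),
                "fingerprint_clusters": overlap_counts(cluster_sets(noisy, clusters)),
            }
            (run_dir / "venn_counts.json").write_text(json.dumps(venn, indent=2))
            done("profile")

        # --- pretrain -----------------------------------------------------
        current = "pretrain"
        enc_cfg = replace(cfg.encoder, seed=_stage_seed(cfg.seed, 5))
        animalia = noisy.select_label(0)
        microbial = LabeledDataset([r for r in noisy if r.label != 0])
        pretrained = pretrain(animalia, microbial, enc_cfg)
        pretrained.save(run_dir / "model_pretrained.npz")
        done("pretrain")

        current = "finetune"
        tuned = finetune(pretrained, noisy)
        tuned.save(run_dir / "model_finetuned.npz")
        done("finetune")

        # --- clean --------------------------------------------------------
        if cfg.run_cleaning:
            current = "clean"
            trainer = model_trainer(replace(cfg.encoder, seed=_stage_seed(cfg.seed, 6)))
            oof_log, flagged = cross_prediction_screen(
                noisy, trainer, cycles=cfg.cycles,
                subset_fraction=cfg.subset_fraction,
                seed=_stage_seed(cfg.seed, 7), coverage=cfg.coverage,
            )
            pd.DataFrame(oof_log.to_rows()).to_csv(run_dir / "oof_log.csv", index=False)
            step1 = noisy.without(flagged)
            # step 2 uses embeddings from a model retrained on step-1 output
            retrain_cfg = replace(cfg.encoder, seed=_stage_seed(cfg.seed, 8))
            step1_model = finetune(
                pretrain(step1.select_label(0),
                         LabeledDataset([r for r in step1 if r.label != 0]),
                         retrain_cfg),
                step1,
            )
            emb = extract_embeddings(step1_model, step1, "last_ffn")
            radius = (
                auto_radius(emb, cfg.radius_quantile, seed=_stage_seed(cfg.seed, 9))
                if cfg.radius == "auto" else float(cfg.radius)
            )
            removed = neighborhood_filter(emb, step1.labels(), radius)
            report = CleaningReport(
                step1_flagged=set(flagged), step2_removed=set(removed),
                cycles=cfg.cycles, subset_fraction=cfg.subset_fraction,
                radius=radius, seed=cfg.seed,
                mean_confidence={cid: [float(x) for x in p]
                                 for cid, p in oof_log.mean_probs().items()},
            )
            report.to_json(run_dir / "cleaning_report.json")
            cleaned = apply_cleaning(noisy, report)
            save_dataset(cleaned, run_dir / "cleaned.csv")
            done("clean")
        else:
            cleaned = noisy
            report = None

        # --- retrain on cleaned data + evaluate ---------------------------
        current = "retrain"
        final_cfg = replace(cfg.encoder, seed=_stage_seed(cfg.seed, 10))
        final_model = finetune(
            pretrain(cleaned.select_label(0),
                     LabeledDataset([r for r in cleaned if r.label != 0]),
                     final_cfg),
            cleaned,
        )
        final_model.save(run_dir / "model_final.npz")
        done("retrain")

        current = "evaluate"
        true_labels = [r.label for r in test_ds]
        probs = final_model.predict_proba(test_ds.smiles)
        gcn_cm = confusion(true_labels, probs.argmax(axis=1))
        metrics = {
            "cleaning_skipped": not cfg.run_cleaning,
            "n_train": len(noisy),
            "n_cleaned": len(cleaned),
            "n_flagged": len(report.step1_flagged) if report else 0,
            "n_removed_step2": len(report.step2_removed) if report else 0,
            "gcn": table_report(gcn_cm).as_dict(),
        }
        if cfg.head in ("svm", "gbt"):
            train_emb = extract_embeddings(final_model, cleaned, "last_ffn")
            head = train_head(train_emb, cleaned.labels(), cfg.head,
                              seed=_stage_seed(cfg.seed, 11))
            test_emb = extract_embeddings(final_model, test_ds, "last_ffn")
            head_pred = head.predict(test_emb.vectors)
            metrics[f"last_ffn_{cfg.head}"] = table_report(
                confusion(true_labels, head_pred)
            ).as_dict()
        (run_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        done("evaluate")

        # --- interpret ----------------------------------------------------
        if cfg.run_interpret:
            current = "interpret"

            def scorer(sub_smiles: str):
                return final_model.predict_proba([sub_smiles])[0]

            rationales = []
            for label in (0, 1, 2):
                picked = [r for r in cleaned if r.label == label][: cfg.rationales_per_class]
                for rec in picked:
                    rationales.extend(
                        mcts_rationales(scorer, rec.smiles, label,
                                        replace(cfg.mcts, seed=_stage_seed(cfg.seed, 12)),
                                        parent_id=rec.id)
                    )
            aggregate_rationales(rationales).to_csv(
                run_dir / "rationales.csv", index=False
            )
            done("interpret")
    except Exception as exc:  # noqa: BLE001 — stage name is part of the contract
        raise StageError(current, exc) from exc

    return run_dir
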