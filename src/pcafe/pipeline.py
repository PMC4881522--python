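"""End-to-end orchestration: normalize -> select -> pair -> discriminate -> q-value.

A run is driven by a :class:`PipelineConfig`, writes every stage's TSV
output plus a machine-readable ``summary.json`` into a run directory, and
logs versions, thresholds and the seed so the directory is self-describing.
A stage failure aborts with the stage name and cause; partial outputs are
retained.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import data_io, pca_fe, regulation_pairs, discrimination, fdr_qvalue

logger = logging.getLogger(__name__)

HUMAN_TAXON = 9606


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    mrna_path: str
    mirna_path: str
    mrna_labels_path: str
    mirna_labels_path: str
    targetscan_path: str
    gene_map_path: str | None = None
    species: int = HUMAN_TAXON
    alpha_pc: float = 0.05
    outlier_threshold: float = 0.01
    regulation_alpha: float = 0.05
    qvalue_threshold: float = 0.01
    #: loadings used by LDA per matrix; None = trial-and-error scan
    L_mrna: int | None = None
    L_mirna: int | None = None
    unlog2_mrna: bool = False
    unlog2_mirna: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha_pc", "outlier_threshold", "regulation_alpha",
                     "qvalue_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("mrna_path", "mirna_path", "mrna_labels_path",
                     "mirna_labels_path", "targetscan_path"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc
    return wrap


def _load_matrix(path, labels_path, do_unlog2: bool) -> data_io.ExpressionMatrix:
    m = data_io.read_expression_table(path, label_path=labels_path)
    if do_unlog2:
        m = data_io.unlog2(m)
    return data_io.normalize_samples(m)


def _analyze_matrix(tag, m, cfg, out):
    result = pca_fe.select_features(
        m, alpha_pc=cfg.alpha_pc, threshold=cfg.outlier_threshold
    )
    result.to_frame().to_csv(out / f"{tag}_features.tsv", sep="\t", index=False)
    result.component_frame().to_csv(out / f"{tag}_components.tsv", sep="\t", index=False)
    qres = fdr_qvalue.qvalues(result.raw_p, threshold=cfg.qvalue_threshold)
    fdr_qvalue.qvalue_frame(result.feature_ids, result.raw_p, qres).to_csv(
        out / f"{tag}_qvalues.tsv", sep="\t", index=False
    )
    return result, qres


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Execute the full pipeline; returns the run directory path."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(cfg), indent=2))

    mrna = _stage("read_mrna")(_load_matrix, cfg.mrna_path, cfg.mrna_labels_path,
                               cfg.unlog2_mrna)
    mirna = _stage("read_mirna")(_load_matrix, cfg.mirna_path, cfg.mirna_labels_path,
                                 cfg.unlog2_mirna)
    targets = _stage("read_targetscan")(
        regulation_pairs.read_targetscan, cfg.targetscan_path, cfg.species
    )
    gene_map = None
    if cfg.gene_map_path:
        frame = pd.read_csv(cfg.gene_map_path, sep="\t", header=None, dtype=str)
        gene_map = dict(zip(frame[0], frame[1]))

    mrna_fe, mrna_q = _stage("select_mrna")(_analyze_matrix, "mrna", mrna, cfg, out)
    mirna_fe, mirna_q = _stage("select_mirna")(_analyze_matrix, "mirna", mirna, cfg, out)

    mrna_calls = _stage("regulation_mrna")(
        regulation_pairs.call_regulation, mrna, mrna_fe.selected_ids,
        cfg.regulation_alpha,
    )
    mirna_calls = _stage("regulation_mirna")(
        regulation_pairs.call_regulation, mirna, mirna_fe.selected_ids,
        cfg.regulation_alpha,
    )
    pairs = _stage("reciprocal_pairs")(
        regulation_pairs.find_reciprocal_pairs, mirna_calls, mrna_calls, targets,
        gene_map,
    )
    regulation_pairs.pairs_to_frame(pairs).to_csv(
        out / "pairs.tsv", sep="\t", index=False
    )

    summary: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "thresholds": {
            "alpha_pc": cfg.alpha_pc,
            "outlier_threshold": cfg.outlier_threshold,
            "regulation_alpha": cfg.regulation_alpha,
            "qvalue_threshold": cfg.qvalue_threshold,
        },
        "counts": {
            "mrna_features": mrna.n_features,
            "mirna_features": mirna.n_features,
            "mrna_selected": int(mrna_fe.selected.sum()),
            "mirna_selected": int(mirna_fe.selected.sum()),
            "mrna_q_significant": int(mrna_q.significant.sum()),
            "mirna_q_significant": int(mirna_q.significant.sum()),
            "mrna_regulation_calls": len(mrna_calls),
            "mirna_regulation_calls": len(mirna_calls),
            "pairs": len(pairs),
        },
        "pi0": {"mrna": mrna_q.pi0, "mirna": mirna_q.pi0},
    }

    discrim_rows = []
    for tag, matrix, fe, L in (
        ("mrna", mrna, mrna_fe, cfg.L_mrna),
        ("mirna", mirna, mirna_fe, cfg.L_mirna),
    ):
        def run_disc():
            if len(fe.selected_ids) < 2:
                raise ValueError(f"fewer than 2 selected {tag} features")
            if L is None:
                return discrimination.scan_L(matrix, fe.selected_ids)
            return discrimination.discriminate(matrix, fe.selected_ids, L)

        res = _stage(f"discriminate_{tag}")(run_disc)
        c = res.confusion
        discrim_rows.append(
            {
                "matrix": tag, "L": res.L,
                "tp": int(c[0, 0]), "fp": int(c[0, 1]),
                "fn": int(c[1, 0]), "tn": int(c[1, 1]),
                "p_value": res.p_value, "odds_ratio": res.odds_ratio,
            }
        )
        summary[f"discrimination_{tag}"] = {
            "L": res.L,
            "confusion": c.tolist(),
            "accuracy": res.accuracy,
            "p_value": res.p_value,
            "odds_ratio": res.odds_ratio if np.isfinite(res.odds_ratio) else "inf",
        }
    pd.DataFrame(discrim_rows).to_csv(out / "discrimination.tsv", sep="\t", index=False)

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline run complete: %s", out)
    return out
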