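"""Synthetic paired mRNA/miRNA data with planted ground truth.

Generates what the pipeline consumes: two case/control expression
matrices (mRNA and miRNA, unmatched cohorts allowed), a conserved-target
map, and the ground truth — which features carry a planted class shift,
in which direction, and which (miRNA, gene) pairs were planted as
reciprocally regulated conserved-target interactions.

The data model is deliberately simple: i.i.d. Gaussian baseline noise per
entry, an additive mean shift of ``effect`` (pre-normalization units) in
the case samples of planted features, and a target map in which each
planted miRNA's conserved targets are drawn mostly from planted mRNAs of
the opposite direction (fraction ``reciprocal_fraction``), padded with
decoy targets among null mRNAs.  Matrices are returned column-normalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, CASE, CONTROL, normalize_samples
from .regulation_pairs import TargetMap, UP, DOWN, normalize_mirna_name

HUMAN_TAXON = 9606


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort pair.

    Defaults are the reference desk-scale scenario: 2000 mRNA and 300
    miRNA features, 20 cases vs 20 controls per matrix, 50/10 planted
    outliers, a between-class shift of 2.0 pre-normalization units on
    unit-variance noise, 20 conserved targets per miRNA of which 80% of a
    planted miRNA's targets are reciprocal planted mRNAs.
    """

    n_mrna: int = 2000
    n_mirna: int = 300
    n_case: int = 20
    n_control: int = 20
    #: miRNA-cohort sample counts; None = same as the mRNA cohort
    n_case_mirna: int | None = None
    n_control_mirna: int | None = None
    n_outlier_mrna: int = 50
    n_outlier_mirna: int = 10
    effect: float = 2.0
    noise_sd: float = 1.0
    targets_per_mirna: int = 20
    reciprocal_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_outlier_mrna > self.n_mrna or self.n_outlier_mirna > self.n_mirna:
            raise ValueError("planted counts exceed feature counts")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not 0 <= self.reciprocal_fraction <= 1:
            raise ValueError("reciprocal_fraction must be in [0, 1]")
        if (
            self.n_outlier_mirna > 0
            and self.reciprocal_fraction > 0
            and self.n_outlier_mrna == 0
        ):
            raise ValueError(
                "infeasible config: reciprocal pairs demanded but no planted mRNAs"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying one generated cohort pair."""

    outlier_mrna: dict[str, str]  # feature id -> planted direction
    outlier_mirna: dict[str, str]
    true_pairs: set[tuple[str, str]] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {
                "outlier_mrna": self.outlier_mrna,
                "outlier_mirna": self.outlier_mirna,
                "true_pairs": sorted(list(p) for p in self.true_pairs),
            },
            indent=2,
        )


def _planted_matrix(
    rng: np.random.Generator,
    prefix: str,
    ids: list[str],
    n_case: int,
    n_control: int,
    planted: dict[str, str],
    effect: float,
    noise_sd: float,
) -> ExpressionMatrix:
    n = len(ids)
    values = rng.normal(0.0, noise_sd, size=(n, n_case + n_control))
    index = {f: i for i, f in enumerate(ids)}
    for fid, direction in planted.items():
        shift = effect if direction == UP else -effect
        values[index[fid], :n_case] += shift
    labels = np.array([CASE] * n_case + [CONTROL] * n_control, dtype=object)
    samples = [f"{prefix}_S{j + 1:03d}" for j in range(n_case + n_control)]
    return normalize_samples(
        ExpressionMatrix(values, ids, samples, labels=labels)
    )


def generate(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, TargetMap, SyntheticTruth]:
    """Generate (mrna, mirna, targets, truth) for one seed.

    Deterministic: a fixed config (seed included) yields byte-identical
    matrices, maps and truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_ids = [f"GENE{i + 1:05d}" for i in range(cfg.n_mrna)]
    mirna_ids = [f"hsa-miR-{i + 1}" for i in range(cfg.n_mirna)]

    planted_genes = rng.choice(cfg.n_mrna, size=cfg.n_outlier_mrna, replace=False)
    planted_mirnas = rng.choice(cfg.n_mirna, size=cfg.n_outlier_mirna, replace=False)
    outlier_mrna = {
        gene_ids[i]: (UP if rng.random() < 0.5 else DOWN) for i in planted_genes
    }
    outlier_mirna = {
        mirna_ids[i]: (UP if rng.random() < 0.5 else DOWN) for i in planted_mirnas
    }

    mrna = _planted_matrix(
        rng, "MR", gene_ids, cfg.n_case, cfg.n_control,
        outlier_mrna, cfg.effect, cfg.noise_sd,
    )
    mirna = _planted_matrix(
        rng, "MI", mirna_ids,
        cfg.n_case_mirna if cfg.n_case_mirna is not None else cfg.n_case,
        cfg.n_control_mirna if cfg.n_control_mirna is not None else cfg.n_control,
        outlier_mirna, cfg.effect, cfg.noise_sd,
    )

    # conserved-target map: planted miRNAs point mostly at opposite-direction
    # planted mRNAs; everything is padded with decoys among null mRNAs
    null_genes = sorted(set(gene_ids) - set(outlier_mrna))
    up_genes = sorted(g for g, d in outlier_mrna.items() if d == UP)
    down_genes = sorted(g for g, d in outlier_mrna.items() if d == DOWN)

    family_to_genes: dict[str, set[str]] = {}
    true_pairs: set[tuple[str, str]] = set()
    for mid in mirna_ids:
        family = normalize_mirna_name(mid)
        chosen: set[str] = set()
        if mid in outlier_mirna:
            opposite = down_genes if outlier_mirna[mid] == UP else up_genes
            want = int(round(cfg.reciprocal_fraction * cfg.targets_per_mirna))
            take = min(want, len(opposite))
            if take:
                picks = rng.choice(len(opposite), size=take, replace=False)
                for k in picks:
                    chosen.add(opposite[k])
                    true_pairs.add((mid, opposite[k]))
        n_decoys = cfg.targets_per_mirna - len(chosen)
        if n_decoys > 0 and null_genes:
            picks = rng.choice(len(null_genes), size=min(n_decoys, len(null_genes)),
                               replace=False)
            chosen.update(null_genes[k] for k in picks)
        family_to_genes[family] = {g.upper() for g in chosen}

    targets = TargetMap(family_to_genes=family_to_genes, species_filter=HUMAN_TAXON)
    truth = SyntheticTruth(
        outlier_mrna=outlier_mrna, outlier_mirna=outlier_mirna, true_pairs=true_pairs
    )
    return mrna, mirna, targets, truth


def write_targetscan_table(targets: TargetMap, path) -> None:
    """Write a TargetMap as a TargetScan-style conserved-family TSV."""
    taxon = targets.species_filter if targets.species_filter is not None else HUMAN_TAXON
    with open(path, "wt") as fh:
        fh.write("miR family\tGene Symbol\tSpecies ID\n")
        for family in sorted(targets.family_to_genes):
            for gene in sorted(targets.family_to_genes[family]):
                fh.write(f"{family}\t{gene}\t{taxon}\n")
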