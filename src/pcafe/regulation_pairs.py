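"""Regulation calls and reciprocal miRNA-mRNA pairing against TargetScan.

Among the features selected by the unsupervised extraction, up/down
regulation between cases and controls is called by Welch t-test with
Benjamini-Hochberg correction over the selected set.  A (miRNA, mRNA)
pair is reported when the gene is a conserved TargetScan target of the
miRNA's family and the two are regulated in opposite directions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix
from .pca_fe import bh_adjust

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"

_COLUMN_ALIASES = {
    "family": ("mir family", "mirna family", "family"),
    "gene": ("gene symbol", "target gene", "gene"),
    "species": ("species id", "species", "taxon id", "taxon"),
}


@dataclass
class RegulationCall:
    """A significantly up- or down-regulated feature (case relative to control)."""

    feature_id: str
    direction: str  # UP or DOWN
    raw_p: float
    adjusted_p: float
    mean_case: float
    mean_control: float


@dataclass
class TargetMap:
    """Conserved miRNA-family -> target-gene map (one species).

    Gene symbols and family keys are case-normalized; mature-miRNA names
    resolve to families first by exact mature-name lookup, then by
    matching the family string itself.
    """

    family_to_genes: dict[str, set[str]]
    mirna_to_family: dict[str, str] = field(default_factory=dict)
    species_filter: int | None = None

    def resolve_family(self, mirna_name: str) -> str | None:
        key = normalize_mirna_name(mirna_name)
        if key in self.mirna_to_family:
            return self.mirna_to_family[key]
        if key in self.family_to_genes:
            return key
        return None

    def targets(self, family: str) -> set[str]:
        return self.family_to_genes.get(family, set())


@dataclass(frozen=True, order=True)
class InteractionPair:
    """A reciprocally regulated (miRNA, target gene) pair."""

    mirna_id: str
    gene_id: str
    mirna_direction: str = field(compare=False)
    gene_direction: str = field(compare=False)
    family: str = field(compare=False)


def call_regulation(
    m: ExpressionMatrix,
    selected: list[str],
    alpha: float = 0.05,
) -> list[RegulationCall]:
    """Welch-test each selected feature; keep BH-adjusted p < ``alpha``.

    The BH universe is the selected feature set only, so regulation calls
    do not depend on how many non-selected features the matrix carries.
    Direction is the sign of (case mean - control mean); the measure-zero
    tie is excluded rather than assigned a direction.
    """
    if not selected:
        logger.warning("call_regulation: empty selected set, no calls made")
        return []
    m.require_labels()
    sub = m.subset_features(list(selected))
    case = sub.case_mask
    xs, ys = sub.values[:, case], sub.values[:, ~case]
    res = stats.ttest_ind(xs, ys, axis=1, equal_var=False)
    raw_p = np.asarray(res.pvalue)
    adjusted = bh_adjust(raw_p)
    mean_case, mean_control = xs.mean(axis=1), ys.mean(axis=1)
    calls = []
    for i, fid in enumerate(sub.feature_ids):
        if adjusted[i] >= alpha:
            continue
        diff = mean_case[i] - mean_control[i]
        if diff == 0.0:
            continue
        calls.append(
            RegulationCall(
                feature_id=fid,
                direction=UP if diff > 0 else DOWN,
                raw_p=float(raw_p[i]),
                adjusted_p=float(adjusted[i]),
                mean_case=float(mean_case[i]),
                mean_control=float(mean_control[i]),
            )
        )
    return calls


def normalize_mirna_name(name: str) -> str:
    """Normalize a mature miRNA name to a family lookup key.

    Strips a species prefix (``hsa-``, ``mmu-`` ...), case-folds, and
    preserves the arm suffix (-3p/-5p): ``"hsa-miR-143-3p"`` -> ``"mir-143-3p"``.
    """
    key = str(name).strip().lower()
    key = re.sub(r"^[a-z]{3,4}-(?=(mir|let))", "", key)
    return key


def read_targetscan(path, species: int) -> TargetMap:
    """Read a TargetScan conserved-family-info style TSV.

    Requires (by case-insensitive alias) a miR-family column, a gene-symbol
    column and a species/taxon column; rows are filtered to ``species`` and
    duplicate (family, gene) rows collapse to set membership.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    lower = {str(c).strip().lower(): c for c in frame.columns}
    cols = {}
    for role, aliases in _COLUMN_ALIASES.items():
        found = next((lower[a] for a in aliases if a in lower), None)
        if found is None:
            raise ValueError(
                f"{path}: missing required column for {role!r} "
                f"(accepted: {', '.join(aliases)})"
            )
        cols[role] = found
    taxa = pd.to_numeric(frame[cols["species"]], errors="coerce")
    frame = frame[taxa == species]
    family_to_genes: dict[str, set[str]] = {}
    for fam, gene in zip(frame[cols["family"]], frame[cols["gene"]]):
        if pd.isna(fam) or pd.isna(gene):
            continue
        key = normalize_mirna_name(fam)
        family_to_genes.setdefault(key, set()).add(str(gene).strip().upper())
    return TargetMap(family_to_genes=family_to_genes, species_filter=species)


def find_reciprocal_pairs(
    mirna_calls: list[RegulationCall],
    mrna_calls: list[RegulationCall],
    targets: TargetMap,
    gene_map: dict[str, str] | None = None,
) -> list[InteractionPair]:
    """Intersect opposite-direction calls with the conserved-target map.

    A pair (miRNA, gene) is emitted iff the gene is among the conserved
    targets of the miRNA's family and the regulation directions are
    opposite (either orientation).  ``gene_map`` optionally translates
    mRNA feature ids (probes) to gene symbols; identity by default.
    Output is deduplicated and sorted by (mirna_id, gene_id).
    """
    unresolved = 0
    by_gene: dict[str, list[RegulationCall]] = {}
    for call in mrna_calls:
        gene = (gene_map or {}).get(call.feature_id, call.feature_id)
        by_gene.setdefault(str(gene).strip().upper(), []).append(call)

    pairs: set[InteractionPair] = set()
    for mirna in mirna_calls:
        family = targets.resolve_family(mirna.feature_id)
        if family is None:
            unresolved += 1
            continue
        for gene in targets.targets(family):
            for mrna in by_gene.get(gene, []):
                if mrna.direction != mirna.direction:
                    pairs.add(
                        InteractionPair(
                            mirna_id=mirna.feature_id,
                            gene_id=gene,
                            mirna_direction=mirna.direction,
                            gene_direction=mrna.direction,
                            family=family,
                        )
                    )
    if unresolved:
        logger.info("find_reciprocal_pairs: %d miRNA names unresolved", unresolved)
    return sorted(pairs)


def pairs_to_frame(pairs: list[InteractionPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": p.mirna_id,
                "gene_id": p.gene_id,
                "mirna_direction": p.mirna_direction,
                "gene_direction": p.gene_direction,
                "family": p.family,
            }
            for p in pairs
        ],
        columns=["mirna_id", "gene_id", "mirna_direction", "gene_direction", "family"],
    )
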