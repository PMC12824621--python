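"""Gene-dosage expression analysis on a TPM matrix.

Triplication of a dosage-sensitive gene predicts increased transcript
abundance.  This module implements the simple cohort comparison used for a
single index sample against a reference cohort: expression is normalized to
a housekeeping gene (ratio normalization removes global library effects),
and the index sample's fold change above the cohort mean (FC) and cohort
z-score (Z) are reported per gene.  Under the naive proportional dosage
model, a gene at total copy number CN is expected at FC = CN/2 (1.5 for a
duplication, 2.0 for a triplication); observed fold changes in real tissues
typically fall somewhat below that expectation.

This is deliberately a plain cohort z-score, not an autoencoder-controlled
outlier model: with a large cohort and a strong dosage effect the two agree
on which genes are outliers, and the simple statistic is transparent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_COHORT_MEAN_TPM = 1.0  # genes below this cohort mean are masked


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    normalized_value: float
    fc: float
    z: float


def housekeeping_normalize(matrix: pd.DataFrame, hk_gene: str) -> pd.DataFrame:
    """Divide every gene's TPM by the sample's housekeeping TPM.

    ``matrix`` is genes x samples.  A zero or missing housekeeping value is
    an error naming the offending sample: the ratio would be undefined.
    """
    if hk_gene not in matrix.index:
        raise ValueError(f"housekeeping gene {hk_gene!r} absent from matrix")
    hk = matrix.loc[hk_gene]
    bad = hk.index[(hk <= 0) | hk.isna()]
    if len(bad):
        raise ValueError(
            f"housekeeping gene {hk_gene!r} has zero/missing TPM in sample "
            f"{bad[0]!r}")
    return matrix.div(hk, axis=1)


def fold_above_mean(normalized: pd.DataFrame, index_sample: str,
                    gene: str) -> float:
    """Index sample's value divided by the mean of all other samples.

    The comparison cohort excludes the index sample, avoiding
    self-contamination of the mean at small cohort sizes.
    """
    cohort = normalized.loc[gene].drop(index_sample)
    if len(cohort) < 3:
        raise ValueError("need a cohort of >= 3 samples besides the index")
    mean = float(cohort.mean())
    if mean == 0:
        raise ValueError(f"cohort mean for {gene!r} is zero; FC undefined")
    return float(normalized.loc[gene, index_sample]) / mean


def expression_zscore(normalized: pd.DataFrame, index_sample: str,
                      gene: str, log_transform: bool = False) -> float:
    """Cohort z-score of the index sample, optionally on log2 values."""
    values = normalized.loc[gene]
    if log_transform:
        values = np.log2(values)
    cohort = values.drop(index_sample)
    sd = float(cohort.std(ddof=1))
    if sd == 0:
        raise ValueError("cohort standard deviation is zero")
    return (float(values[index_sample]) - float(cohort.mean())) / sd


def expected_dosage_fc(total_cn: int) -> float:
    """Naive proportional dosage model: FC = CN / 2."""
    if total_cn < 0:
        raise ValueError("copy number must be >= 0")
    return total_cn / 2.0


def analyze(
    matrix: pd.DataFrame,
    hk_gene: str,
    index_sample: str,
    log_transform_z: bool = False,
    min_cohort_mean_tpm: float = MIN_COHORT_MEAN_TPM,
) -> list[ExpressionResult]:
    """Per-gene FC and Z for the index sample against the cohort.

    Genes whose raw cohort mean TPM falls below ``min_cohort_mean_tpm`` are
    masked (ratio statistics on barely expressed genes are unstable).
    """
    if index_sample not in matrix.columns:
        raise ValueError(f"index sample {index_sample!r} absent from matrix")
    normalized = housekeeping_normalize(matrix, hk_gene)
    cohort_raw_mean = matrix.drop(columns=index_sample).mean(axis=1)
    results = []
    for gene in matrix.index:
        if cohort_raw_mean[gene] < min_cohort_mean_tpm:
            continue
        cohort_norm = normalized.loc[gene].drop(index_sample)
        if float(cohort_norm.std(ddof=1)) == 0:
            continue  # degenerate, e.g. the housekeeping gene itself
        fc = fold_above_mean(normalized, index_sample, gene)
        z = expression_zscore(normalized, index_sample, gene, log_transform_z)
        results.append(ExpressionResult(
            gene=str(gene),
            normalized_value=float(normalized.loc[gene, index_sample]),
            fc=fc, z=z))
    return results


def results_to_table(results: list[ExpressionResult]) -> pd.DataFrame:
    rows = [[r.gene, r.normalized_value, r.fc, r.z] for r in results]
    return pd.DataFrame(rows, columns=["gene", "normalized_value", "FC", "Z"])
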