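"""Replicate averaging and reference-gene normalization of qPCR Ct values.

Raw input is a long table of replicate cycle-threshold readings. Replicates
are averaged arithmetically per (patient, gene); each panel gene's mean Ct
is then divided by the patient's beta-actin mean Ct, giving the normalized
expression value CtS = Ct(gene)/Ct(actin). The canonical CtS is the bare
ratio; reporting conventionally multiplies by 1000. Classification is
invariant to that choice (an affine feature rescaling is absorbed by the
fitted discriminant coefficients), so the scale is a presentation option.

No replicate QC rejection is applied; replicates whose range exceeds one
cycle are only flagged via logging.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .panels import PANEL14, REFERENCE_GENE, GenePanel

logger = logging.getLogger(__name__)

__all__ = ["average_replicates", "normalize", "normalize_table"]

REQUIRED_COLUMNS = ("patient_id", "gene", "replicate", "ct")


def average_replicates(measurements: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of replicate Ct readings per (patient, gene).

    Parameters
    ----------
    measurements : long DataFrame with columns patient_id, gene, replicate, ct.

    Returns
    -------
    DataFrame indexed by (patient_id, gene) with columns ``ct_mean`` and
    ``n_replicates`` (replicate count retained for QC reporting).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns: {missing}")
    if measurements.empty:
        raise ValueError("no measurements supplied")
    if (measurements["ct"] <= 0).any():
        bad = measurements.loc[measurements["ct"] <= 0]
        raise ValueError(
            f"non-positive Ct readings for "
            f"{sorted(set(zip(bad['patient_id'], bad['gene'])))}"
        )
    grouped = measurements.groupby(["patient_id", "gene"], sort=True)["ct"]
    out = grouped.agg(ct_mean="mean", n_replicates="size")
    spread = grouped.agg(lambda s: s.max() - s.min())
    wide_spread = spread[spread > 1.0]
    if not wide_spread.empty:
        logger.warning(
            "replicate Ct range exceeds 1 cycle for %d (patient, gene) pairs: %s",
            len(wide_spread),
            list(wide_spread.index[:10]),
        )
    return out


def normalize(
    mean_cts: Mapping[str, float],
    reference_gene: str = REFERENCE_GENE,
    scale: float = 1000,
) -> pd.Series:
    """Normalize one patient's mean Ct values against the reference gene.

    Returns CtS[g] = scale * Ct(g) / Ct(reference) for every non-reference
    gene; the reference itself is excluded from the output.
    """
    cts = pd.Series(dict(mean_cts), dtype=float)
    if reference_gene not in cts.index or not cts[reference_gene] > 0:
        raise ValueError(
            f"cannot normalize: reference gene {reference_gene!r} missing "
            "or non-positive"
        )
    ref = cts[reference_gene]
    out = scale * cts.drop(reference_gene) / ref
    out.name = "cts"
    return out


def normalize_table(
    measurements: pd.DataFrame,
    panel: GenePanel = PANEL14,
    reference_gene: str = REFERENCE_GENE,
    scale: float = 1000,
) -> pd.DataFrame:
    """Full normalization of a replicate-level Ct table to a CtS matrix.

    Averages replicates, then normalizes each patient against the reference
    channel. Returns a wide DataFrame (patients x panel genes, panel order).
    Patients missing any required gene (or the reference) raise with a
    listing of the missing (patient, gene) pairs.
    """
    means = average_replicates(measurements)["ct_mean"].unstack("gene")
    required = list(panel) + [reference_gene]
    missing_pairs = [
        (patient, gene)
        for gene in required
        for patient in means.index[
            means[gene].isna() if gene in means.columns else slice(None)
        ]
    ]
    if missing_pairs:
        raise ValueError(
            f"missing replicates for (patient, gene) pairs: {missing_pairs}"
        )
    ratio = means[list(panel)].div(means[reference_gene], axis=0) * scale
    ratio.columns.name = None
    return ratio
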