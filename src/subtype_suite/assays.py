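"""Deterministic assay calculators: absolute telomere qPCR, TRF calibration,
delta-delta-Ct fold change, and RRBS promoter/gene methylation summaries.

Absolute telomere length uses synthetic oligonucleotide standards for the
telomere (84 bp) and single-copy-gene (81 bp) reactions: each standard
curve is an ordinary least-squares fit of Ct against log10(molecules),
sample Cts are converted back to molecule counts, telomere kilobases are
molecules x oligo length / 1000, and the denominator is diploid genome
copies (single-copy-gene molecules / 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

TELOMERE_OLIGO_BP = 84
SCG_OLIGO_BP = 81


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("invalid curve: standard-curve slope must be negative")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency implied by the slope (2.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope)

    def molecules(self, ct) -> np.ndarray:
        """Invert the curve: Ct -> molecule count."""
        return 10.0 ** ((np.asarray(ct, dtype=float) - self.intercept) / self.slope)

    def ct(self, molecules) -> np.ndarray:
        return self.intercept + self.slope * np.log10(np.asarray(molecules, dtype=float))


def fit_standard_curve(molecules, cts) -> StandardCurve:
    """OLS fit of Ct vs log10(molecules) over the dilution series."""
    molecules = np.asarray(molecules, dtype=float)
    cts = np.asarray(cts, dtype=float)
    if molecules.size < 3:
        raise ValueError("need at least 3 standard dilutions")
    if (molecules <= 0).any():
        raise ValueError("molecule counts must be positive")
    fit = sps.linregress(np.log10(molecules), cts)
    return StandardCurve(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def telomere_qpcr_length(sample_cts: pd.DataFrame,
                         telomere_standards: pd.DataFrame,
                         scg_standards: pd.DataFrame,
                         oligo_bp: tuple[int, int] = (TELOMERE_OLIGO_BP, SCG_OLIGO_BP),
                         ) -> pd.DataFrame:
    """Absolute telomere length (kb per diploid genome) from qPCR Cts.

    ``sample_cts`` has columns sample_id, target (telomere | scg), ct;
    replicate Cts per sample/target are averaged before conversion. The
    standards tables have columns molecules, ct. Sample Cts outside the
    standard range only raise a warning.
    """
    tel_curve = fit_standard_curve(telomere_standards["molecules"],
                                   telomere_standards["ct"])
    scg_curve = fit_standard_curve(scg_standards["molecules"], scg_standards["ct"])
    mean_ct = (sample_cts.groupby(["sample_id", "target"])["ct"].mean()
               .unstack("target"))
    for target in ("telomere", "scg"):
        if target not in mean_ct.columns:
            raise ValueError(f"sample table is missing target {target!r}")
    for target, std in (("telomere", telomere_standards), ("scg", scg_standards)):
        lo, hi = std["ct"].min(), std["ct"].max()
        out = (mean_ct[target] < lo) | (mean_ct[target] > hi)
        if out.any():
            logger.warning("%d %s sample Ct(s) outside the standard range",
                           int(out.sum()), target)
    mol_tel = tel_curve.molecules(mean_ct["telomere"])
    mol_scg = scg_curve.molecules(mean_ct["scg"])
    telomere_kb = mol_tel * oligo_bp[0] / 1000.0
    genomes = mol_scg / 2.0
    return pd.DataFrame({
        "telomere_molecules": mol_tel,
        "scg_molecules": mol_scg,
        "diploid_genomes": genomes,
        "length_kb": telomere_kb / genomes,
    }, index=mean_ct.index)


@dataclass
class LinearCalibration:
    slope: float
    intercept: float
    r_squared: float

    def __call__(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def calibrate_qpcr_to_trf(qpcr_lengths, trf_lengths) -> LinearCalibration:
    """OLS map from qPCR telomere length to the Southern-blot TRF scale."""
    x = np.asarray(qpcr_lengths, dtype=float)
    y = np.asarray(trf_lengths, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors required")
    if x.size < 3:
        raise ValueError("need at least 3 paired measurements")
    if x.std() == 0:
        raise ValueError("zero variance in qPCR lengths")
    fit = sps.linregress(x, y)
    return LinearCalibration(float(fit.slope), float(fit.intercept),
                             float(fit.rvalue**2))


def ddct_fold_change(ct_target_test: float, ct_ref_test: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Fold change by the delta-delta-Ct method: 2^-((dCt_test) - (dCt_ctrl))."""
    cts = (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(cts)):
        raise ValueError("non-finite Ct value")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def promoters_from_tss(tss_table: pd.DataFrame, flank: int = 2000) -> pd.DataFrame:
    """Symmetric TSS +/- flank promoter regions (strand-independent)."""
    out = pd.DataFrame({
        "name": tss_table["name"],
        "chrom": tss_table["chrom"],
        "start": (tss_table["pos"].astype(int) - flank).clip(lower=0),
        "end": tss_table["pos"].astype(int) + flank,
    })
    return out


def rrbs_region_methylation(cpg_table: pd.DataFrame, regions: pd.DataFrame,
                            min_reads: int = 10, min_cpgs: int = 5) -> pd.DataFrame:
    """Mean CpG methylation per region with coverage filters.

    CpGs with fewer than ``min_reads`` reads are excluded; regions keeping
    fewer than ``min_cpgs`` CpGs are dropped. The region value is the
    unweighted mean of surviving CpG methylation fractions. Regions use
    0-based half-open coordinates.
    """
    frac = cpg_table["meth_fraction"].astype(float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("meth_fraction outside [0, 1]")
    covered = cpg_table[cpg_table["reads"] >= min_reads]
    rows = []
    for region in regions.itertuples(index=False):
        hit = covered[(covered["chrom"] == region.chrom)
                      & (covered["pos"] >= region.start)
                      & (covered["pos"] < region.end)]
        if len(hit) < min_cpgs:
            continue
        rows.append({"name": region.name, "n_cpgs": len(hit),
                     "mean_methylation": float(hit["meth_fraction"].mean())})
    return pd.DataFrame(rows, columns=["name", "n_cpgs", "mean_methylation"])
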