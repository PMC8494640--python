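"""Differential isoform usage between two species.

Usage of an isoform within a cell subclass is its genic proportion
P = isoform TPM / gene TPM. The cross-species shift statistic is

    R = (P_human - P_mouse) / (P_human + P_mouse)

which lies in [-1, 1], is antisymmetric under a species swap, and maps a
usage ratio rho = P_human/P_mouse to R = (rho - 1)/(rho + 1): a ninefold
change in usage corresponds exactly to |R| > 0.8.

Uncertainty on P is propagated from the quantifier's 95% confidence
intervals on isoform TPM, treated as symmetric normal intervals:
sd(TPM) = (ci_high - ci_low)/(2 x 1.96) and sd(P) = sd(TPM)/gene TPM. The
test statistic (P_human - P_mouse)/sqrt(sd_h^2 + sd_m^2) yields a
two-sided normal p-value, Bonferroni-adjusted by the number of tested
(medium-to-highly expressed) isoforms in the subclass. An isoform is
tested when its abundance exceeds ``tpm_min`` in both species and, in at
least one species, it additionally has genic proportion above
``prop_min``.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Z_95",
    "compute_proportions",
    "shift_and_test",
    "summarize_switching",
    "ratio_to_shift",
]

Z_95 = 1.96  # normal quantile matching a 95% confidence interval


def ratio_to_shift(rho: np.ndarray) -> np.ndarray:
    """Map a usage ratio P1/P2 to the shift statistic R = (rho-1)/(rho+1)."""
    rho = np.asarray(rho, dtype=float)
    return (rho - 1.0) / (rho + 1.0)


def compute_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Genic proportions P and their standard deviations per table row.

    Adds ``P`` (isoform TPM / gene TPM, clipped to [0, 1]), ``sd_P``
    (CI-derived) and ``valid``. Rows with gene TPM = 0 but isoform TPM > 0
    are marked invalid; isoform TPM exceeding gene TPM triggers a soft
    warning only (quantification noise).
    """
    required = {"isoform_id", "species", "subclass", "tpm",
                "tpm_ci_low", "tpm_ci_high", "gene_tpm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"isoform table lacks columns: {sorted(missing)}")
    out = table.copy()
    gene = out["gene_tpm"].to_numpy(dtype=float)
    tpm = out["tpm"].to_numpy(dtype=float)
    invalid = (gene == 0) & (tpm > 0)
    if invalid.any():
        warnings.warn(
            f"{invalid.sum()} rows have isoform TPM > 0 with gene TPM = 0; "
            "marked invalid"
        )
    soft = tpm > gene * (1 + 1e-9)
    if (soft & ~invalid).any():
        warnings.warn(
            f"{(soft & ~invalid).sum()} rows have isoform TPM exceeding "
            "gene TPM (clipped)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(gene > 0, tpm / gene, 0.0)
        sd_tpm = (
            out["tpm_ci_high"].to_numpy(float) - out["tpm_ci_low"].to_numpy(float)
        ) / (2 * Z_95)
        sd_p = np.where(gene > 0, sd_tpm / gene, np.nan)
    out["P"] = np.clip(p, 0.0, 1.0)
    out["sd_P"] = sd_p
    out["valid"] = ~invalid
    return out


def shift_and_test(
    table: pd.DataFrame,
    species: tuple[str, str] = ("human", "mouse"),
    tpm_min: float = 10.0,
    prop_min: float = 0.2,
) -> pd.DataFrame:
    """Per (isoform, subclass) usage shift R with CI-propagated p-values.

    Returns one row per isoform x subclass present in both species, with
    proportions, R, the normal-test p-value, the per-subclass Bonferroni
    adjustment (multiplied by the number of tested isoforms in that
    subclass, capped at 1), and tested/switch flags
    (switch = tested and |R| > 0.8, i.e. a more-than-ninefold usage change).
    """
    if "P" not in table.columns:
        table = compute_proportions(table)
    sp_a, sp_b = species
    cols = ["isoform_id", "gene_id", "subclass", "tpm", "P", "sd_P", "valid"]
    cols = [c for c in cols if c in table.columns]
    wide = None
    for sp, suffix in ((sp_a, "_a"), (sp_b, "_b")):
        sub = table.loc[table["species"] == sp, cols].rename(
            columns={
                "tpm": f"tpm{suffix}", "P": f"P{suffix}",
                "sd_P": f"sd_P{suffix}", "valid": f"valid{suffix}",
            }
        )
        wide = sub if wide is None else wide.merge(
            sub, on=[c for c in ("isoform_id", "gene_id", "subclass") if c in cols],
            how="inner",
        )
    if wide is None or wide.empty:
        raise ValueError("no isoforms shared between the two species")

    pa, pb = wide["P_a"].to_numpy(), wide["P_b"].to_numpy()
    sa, sb = wide["sd_P_a"].to_numpy(), wide["sd_P_b"].to_numpy()
    ta, tb = wide["tpm_a"].to_numpy(), wide["tpm_b"].to_numpy()
    valid = wide["valid_a"].to_numpy() & wide["valid_b"].to_numpy()

    tested = (
        valid
        & (ta > tpm_min)
        & (tb > tpm_min)
        & (((ta > tpm_min) & (pa > prop_min)) | ((tb > tpm_min) & (pb > prop_min)))
    )

    denom = pa + pb
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (pa - pb) / denom, 0.0)
    sd = np.sqrt(sa**2 + sb**2)
    p_val = np.ones(len(wide))
    degenerate = (sd == 0) & (pa != pb)
    if degenerate.any():
        warnings.warn(
            f"{degenerate.sum()} isoforms have zero propagated variance with "
            "unequal proportions; their p-values are 0"
        )
        p_val[degenerate] = 0.0
    ok = sd > 0
    z = np.zeros(len(wide))
    z[ok] = (pa[ok] - pb[ok]) / sd[ok]
    p_val[ok] = 2 * stats.norm.sf(np.abs(z[ok]))

    out = wide.copy()
    out[f"P_{sp_a}"] = pa
    out[f"P_{sp_b}"] = pb
    out[f"sd_P_{sp_a}"] = sa
    out[f"sd_P_{sp_b}"] = sb
    out["R"] = r
    out["p"] = p_val
    out["tested"] = tested
    # Bonferroni within subclass over tested isoforms
    n_tested = out.groupby("subclass")["tested"].transform("sum")
    out["p_bonf"] = np.where(
        tested, np.minimum(p_val * n_tested, 1.0), np.nan
    )
    out["switch"] = tested & (np.abs(r) > 0.8)
    drop = [c for c in out.columns if c.endswith(("_a", "_b"))]
    return out.drop(columns=drop)


def summarize_switching(results: pd.DataFrame) -> pd.DataFrame:
    """Per-subclass fraction of tested isoforms that switch usage.

    A subclass with zero tested isoforms reports a missing fraction.
    """
    if "tested" not in results.columns:
        raise ValueError("results must come from shift_and_test")
    rows = []
    for subclass, grp in results.groupby("subclass"):
        n_tested = int(grp["tested"].sum())
        n_switch = int(grp["switch"].sum())
        rows.append(
            {
                "subclass": subclass,
                "n_tested": n_tested,
                "n_switch": n_switch,
                "switch_fraction": n_switch / n_tested if n_tested else np.nan,
            }
        )
    return pd.DataFrame(rows)
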