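"""Quantitative validation arithmetic.

ChIP-PCR enrichment as a ratio of ratios (target vs control amplicon, ChIP
vs input), qRT-PCR relative expression by the delta-delta-Ct method with a
reference amplicon (an 18S rRNA analogue), and read-mapping percentage
summaries.  Amplification efficiency is assumed perfect (a factor of 2 per
cycle) unless stated otherwise; Ct replicates are averaged on the Ct scale
before any transformation.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def ct_to_abundance(ct: float, efficiency: float = 2.0) -> float:
    """Relative template abundance implied by a cycle-threshold value."""
    if ct <= 0:
        raise ValueError("Ct values must be positive")
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1")
    return efficiency ** (-ct)


def chip_pcr_enrichment(
    target_chip: float,
    control_chip: float,
    target_input: float,
    control_input: float,
    from_ct: bool = False,
    efficiency: float = 2.0,
) -> float:
    """ChIP-PCR enrichment of a target region over a control region.

    The ratio of target to control abundance in the ChIP sample, relative to
    the same ratio in the input sample.  With ``from_ct=True`` the four
    arguments are Ct values and are converted assuming the given efficiency.
    """
    values = [target_chip, control_chip, target_input, control_input]
    if from_ct:
        values = [ct_to_abundance(v, efficiency) for v in values]
    if any(v <= 0 for v in values):
        raise ValueError("abundances must be positive")
    tc, cc, ti, ci = values
    return (tc / cc) / (ti / ci)


def relative_expression_log2(
    ct_target_a: float,
    ct_ref_a: float,
    ct_target_b: float,
    ct_ref_b: float,
) -> float:
    """Log2 expression ratio of strain A over strain B (delta-delta Ct).

    The target Ct is normalized by the reference amplicon within each
    strain; one cycle equals a 2-fold abundance difference.
    """
    return -((ct_target_a - ct_ref_a) - (ct_target_b - ct_ref_b))


def mapping_summary(raw_reads: int, mapped_reads: int) -> float:
    """Percentage of reads mapped, rounded to two decimals."""
    if raw_reads <= 0 or mapped_reads <= 0:
        raise ValueError("read counts must be positive")
    if mapped_reads > raw_reads:
        raise ValueError("mapped reads cannot exceed raw reads")
    return round(100.0 * mapped_reads / raw_reads, 2)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (amplicon, sample, replicate, ct), averaging replicates.

    Returns a DataFrame indexed by (amplicon, sample) with a ``ct`` column.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"amplicon", "sample", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df.groupby(["amplicon", "sample"], sort=True)[["ct"]].mean()
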