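"""Reading, validation and harmonization of GWAS summary statistics.

Summary-statistics files in the wild use many header dialects; ``read_sumstats``
maps common synonyms onto the canonical columns
``SNP CHR BP A1 A2 BETA SE P N FRQ INFO`` and drops (while counting) rows whose
mandatory fields cannot be parsed.  ``harmonize`` aligns a table to a target
genotype panel by marker id, re-signs effects when the effect/other alleles are
swapped relative to the panel, and applies marker QC: nucleotide-inconsistent
records, strand-ambiguous palindromic SNPs (A/T, C/G), markers with target
minor-allele frequency below 1%, and poorly imputed markers (info <= 0.70) are
dropped, each with a provenance flag so QC counts exactly partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypePanel

__all__ = ["read_sumstats", "harmonize", "qc_report", "HarmonizedSumStats", "COLUMN_SYNONYMS"]

#: recognized header synonyms (matched case-insensitively), canonical -> aliases
COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "SNP": ("snp", "rsid", "rs_id", "markername", "marker", "snpid", "id"),
    "CHR": ("chr", "chrom", "chromosome"),
    "BP": ("bp", "pos", "position", "base_pair"),
    "A1": ("a1", "effect_allele", "allele1", "ea", "alt"),
    "A2": ("a2", "other_allele", "allele2", "oa", "ref", "non_effect_allele"),
    "BETA": ("beta", "b", "effect", "effect_size", "beta1"),
    "OR": ("or", "odds_ratio", "oddsratio"),
    "SE": ("se", "stderr", "standard_error"),
    "P": ("p", "pval", "p_value", "pvalue", "p_bolt_lmm"),
    "N": ("n", "samplesize", "sample_size", "n_total", "neff"),
    "FRQ": ("frq", "freq", "eaf", "maf", "af", "effect_allele_frequency", "freq1"),
    "INFO": ("info", "imputation_quality", "rsq", "info_score"),
}

_MANDATORY = ["SNP", "A1", "A2", "BETA", "SE", "P"]

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}
_VALID_ALLELES = {"A", "C", "G", "T"}


def _resolve_columns(header: list[str], dialect: dict[str, str] | None) -> dict[str, str]:
    """Map canonical names to actual file columns; ``dialect`` overrides."""
    lower = {c.lower(): c for c in header}
    mapping: dict[str, str] = {}
    for canon, aliases in COLUMN_SYNONYMS.items():
        for alias in (canon.lower(), *aliases):
            if alias in lower:
                mapping[canon] = lower[alias]
                break
    if dialect:
        for canon, col in dialect.items():
            if col not in header:
                raise ValueError(f"dialect maps {canon!r} to missing column {col!r}")
            mapping[canon.upper()] = col
    return mapping


def read_sumstats(path: str | Path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tab- or whitespace-delimited summary-statistics file.

    Returns a table with canonical columns; an ``OR`` column (and no ``BETA``)
    is converted to the log scale, since polygenic scores are linear in
    effects.  Rows with unparseable mandatory fields or nonpositive SE are
    dropped; counts are recorded in ``table.attrs["qc"]``.

    Parameters
    ----------
    path
        Existing text file with a header line.
    dialect
        Optional explicit mapping ``{"BETA": "my_effect_col", ...}`` taking
        precedence over the built-in synonyms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if raw.empty and len(raw.columns) == 0:
        raise ValueError(f"empty summary-statistics file: {path}")
    mapping = _resolve_columns(list(raw.columns), dialect)
    has_beta = "BETA" in mapping
    has_or = "OR" in mapping
    missing = [c for c in _MANDATORY if c not in mapping and not (c == "BETA" and has_or)]
    if missing:
        raise ValueError(f"missing mandatory columns {missing} in {path} (header: {list(raw.columns)})")

    out = pd.DataFrame()
    out["SNP"] = raw[mapping["SNP"]].astype(str).str.strip()
    for canon in ("A1", "A2"):
        out[canon] = raw[mapping[canon]].astype(str).str.strip().str.upper()
    numeric = {"SE": "SE", "P": "P"}
    if has_beta:
        out["BETA"] = pd.to_numeric(raw[mapping["BETA"]], errors="coerce")
    else:
        odds = pd.to_numeric(raw[mapping["OR"]], errors="coerce")
        with np.errstate(invalid="ignore", divide="ignore"):
            out["BETA"] = np.log(odds.where(odds > 0))
    for canon in numeric.values():
        out[canon] = pd.to_numeric(raw[mapping[canon]], errors="coerce")
    for canon in ("CHR", "BP", "N", "FRQ", "INFO"):
        if canon in mapping:
            out[canon] = pd.to_numeric(raw[mapping[canon]], errors="coerce")

    n_in = len(out)
    ok = (
        out["SNP"].ne("")
        & out["BETA"].notna()
        & out["SE"].notna()
        & (out["SE"] > 0)
        & out["P"].notna()
        & (out["P"] > 0)
        & (out["P"] <= 1)
        & out["A1"].ne(out["A2"])
    )
    table = out[ok].reset_index(drop=True)
    dup = table["SNP"].duplicated(keep="first")
    table = table[~dup].reset_index(drop=True)
    table.attrs["qc"] = {
        "n_input": n_in,
        "n_dropped_parse": int((~ok).sum()),
        "n_dropped_duplicate": int(dup.sum()),
        "n_retained": len(table),
        "or_converted": bool(not has_beta and has_or),
    }
    if table.empty:
        raise ValueError(f"no valid records in {path}")
    return table


@dataclass
class HarmonizedSumStats:
    """Summary statistics aligned to a target panel with per-record provenance.

    ``table`` holds every input record with a ``status`` column: ``matched``,
    ``flipped`` (alleles swapped, beta negated) or ``dropped:<reason>`` with
    reason one of unmatched, allele_mismatch, ambiguous, low_maf, low_info.
    ``retained`` is the kept subset with harmonized BETA/A1/A2, ordered as in
    the input.
    """

    table: pd.DataFrame
    n_input: int

    @property
    def retained(self) -> pd.DataFrame:
        keep = self.table[~self.table["status"].str.startswith("dropped")]
        return keep.reset_index(drop=True)

    def weights_for_panel(self, panel: GenotypePanel) -> np.ndarray:
        """Per-panel-variant effect vector (zero where no record retained),
        signed for the panel's counted allele — ready for score computation."""
        w = np.zeros(panel.n_snps)
        idx = pd.Series(np.arange(panel.n_snps), index=panel.variants["snp_id"])
        kept = self.retained
        w[idx.loc[kept["SNP"]].to_numpy()] = kept["BETA"].to_numpy()
        return w


def harmonize(
    sumstats: pd.DataFrame,
    panel: GenotypePanel,
    maf_min: float = 0.01,
    info_min: float = 0.70,
    drop_ambiguous: bool = True,
) -> HarmonizedSumStats:
    """Align summary statistics to the target panel's variants and apply QC.

    Records are matched on marker id.  If (A1, A2) equals the panel's allele
    pair the effect is kept as-is; if swapped, the effect is negated and the
    alleles exchanged so that BETA always refers to the panel's counted
    allele; any other allele combination is a nucleotide inconsistency and is
    dropped.  Strand-ambiguous A/T and C/G markers are dropped when
    ``drop_ambiguous`` (the conservative standard, since strand cannot be
    verified for palindromes).  Markers with target MAF < ``maf_min`` are
    dropped (boundary kept); markers with info <= ``info_min`` are dropped
    when an INFO column is present (records lacking info pass).
    """
    if sumstats.empty:
        raise ValueError("empty summary-statistics table")
    pv = panel.variants.set_index("snp_id")
    tab = sumstats.copy().reset_index(drop=True)
    status = np.full(len(tab), "matched", dtype=object)

    in_panel = tab["SNP"].isin(pv.index).to_numpy()
    status[~in_panel] = "dropped:unmatched"
    if not in_panel.any():
        raise ValueError("zero overlapping variants between summary statistics and panel "
                         "(marker id scheme mismatch?)")

    sub = tab.loc[in_panel]
    ref = pv.loc[sub["SNP"]]
    pa1 = ref["a1"].to_numpy()
    pa2 = ref["a2"].to_numpy()
    a1 = sub["A1"].to_numpy()
    a2 = sub["A2"].to_numpy()
    same = (a1 == pa1) & (a2 == pa2)
    swapped = (a1 == pa2) & (a2 == pa1)
    bad_alleles = ~(same | swapped) | ~np.isin(a1, list(_VALID_ALLELES)) | ~np.isin(a2, list(_VALID_ALLELES))
    ambiguous = np.array([frozenset((x, y)) in _AMBIGUOUS for x, y in zip(a1, a2)])
    low_maf = ref["maf"].to_numpy() < maf_min
    if "INFO" in sub.columns:
        info = sub["INFO"].to_numpy(dtype=float)
        low_info = np.where(np.isnan(info), False, info <= info_min)
    else:
        low_info = np.zeros(len(sub), dtype=bool)

    sub_status = np.full(len(sub), "matched", dtype=object)
    sub_status[swapped] = "flipped"
    # precedence: inconsistency > ambiguity > MAF > info
    sub_status[low_info] = "dropped:low_info"
    sub_status[low_maf] = "dropped:low_maf"
    if drop_ambiguous:
        sub_status[ambiguous] = "dropped:ambiguous"
    sub_status[bad_alleles] = "dropped:allele_mismatch"
    status[in_panel] = sub_status

    tab["status"] = status
    flip = (status == "flipped")
    tab.loc[flip, "BETA"] = -tab.loc[flip, "BETA"].to_numpy()
    if "FRQ" in tab.columns:
        tab.loc[flip, "FRQ"] = 1.0 - tab.loc[flip, "FRQ"].to_numpy()
    old_a1 = tab.loc[flip, "A1"].to_numpy()
    tab.loc[flip, "A1"] = tab.loc[flip, "A2"].to_numpy()
    tab.loc[flip, "A2"] = old_a1
    tab.loc[flip, "status"] = "flipped"
    return HarmonizedSumStats(table=tab, n_input=len(tab))


_REASONS = ["unmatched", "allele_mismatch", "ambiguous", "low_maf", "low_info"]


def qc_report(harmonized: HarmonizedSumStats) -> dict[str, int]:
    """Counts per drop reason; together with ``retained`` and ``flipped`` they
    partition the input record count exactly."""
    status = harmonized.table["status"]
    counts = {r: int((status == f"dropped:{r}").sum()) for r in _REASONS}
    counts["flipped"] = int((status == "flipped").sum())
    counts["matched"] = int((status == "matched").sum())
    counts["retained"] = counts["matched"] + counts["flipped"]
    counts["n_input"] = harmonized.n_input
    assert counts["retained"] + sum(counts[r] for r in _REASONS) == counts["n_input"]
    return counts


def write_qc_report(counts: dict[str, int], path: str | Path) -> None:
    pd.DataFrame([counts]).T.rename(columns={0: "count"}).to_csv(path, sep="\t")
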