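"""GWAS summary-statistic I/O, validation, and harmonization.

The unit of all downstream MR computation is the
:class:`HarmonizedInstrumentSet`: per-SNP exposure and outcome effect
estimates (optionally plus mediators such as BMI or SHBG) aligned to a
common effect allele, with an exclusion log accounting for every variant
that entered but was dropped.

Tables use a GWAS-SSF-like tab-separated dialect with columns
``variant_id, chr, pos, effect_allele, other_allele, eaf, beta, se``
(``chr``/``pos`` are carried as opaque metadata; matching is by variant
ID only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("variant_id", "effect_allele", "other_allele", "eaf", "beta", "se")
VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default half-width of the allele-frequency window around 0.5 inside which
#: palindromic (A/T, C/G) variants are considered strand-ambiguous and dropped
DEFAULT_PALINDROME_EAF_WINDOW = 0.08


class SumstatsError(ValueError):
    """Malformed or invalid summary-statistics input."""


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.map(_COMPLEMENT)


def validate_assoc_table(df: pd.DataFrame, name: str = "sumstats") -> pd.DataFrame:
    """Validate and clean an association table.

    Enforces the AssocTable invariants: required columns present, unique
    variant IDs, alleles in {A,C,G,T}, eaf in (0,1), strictly positive SE.
    Rows with missing beta/se or non-positive se are dropped with a logged
    count; structural problems (missing column, duplicate IDs, non-numeric
    beta) raise :class:`SumstatsError`.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SumstatsError(f"{name}: missing required column '{col}'")
    df = df.copy()
    for col in ("eaf", "beta", "se"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if col == "beta" and bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise SumstatsError(f"{name}: non-numeric beta at line {line}")
        df[col] = coerced
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise SumstatsError(f"{name}: duplicate variant_id '{dup}'")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
        bad_allele = ~df[col].isin(VALID_ALLELES)
        if bad_allele.any():
            raise SumstatsError(
                f"{name}: invalid {col} "
                f"'{df.loc[bad_allele, col].iloc[0]}' (expected A/C/G/T)"
            )
    keep = df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
    keep &= df["eaf"].notna() & (df["eaf"] > 0) & (df["eaf"] < 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d row(s) with missing/invalid beta, se or eaf", name, n_dropped)
    return df.loc[keep].reset_index(drop=True)


def read_sumstats(path, dialect: str = "gwas-ssf") -> pd.DataFrame:
    """Read a tab-separated summary-statistics file into a validated table.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with a header containing at least
        ``variant_id, effect_allele, other_allele, eaf, beta, se``.
    dialect : str
        Reserved for future dialects; only ``"gwas-ssf"`` is recognised.
    """
    if dialect != "gwas-ssf":
        raise SumstatsError(f"unknown sumstats dialect '{dialect}'")
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    return validate_assoc_table(df, name=str(path))


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write an association table in the same tab-separated dialect."""
    cols = [c for c in ("variant_id", "chr", "pos", "effect_allele", "other_allele",
                        "eaf", "beta", "se") if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def apply_surrogate_map(table: pd.DataFrame, surrogates: pd.DataFrame) -> pd.DataFrame:
    """Replace variant IDs by precomputed LD surrogates before harmonization.

    ``surrogates`` has two columns (original ID, surrogate ID). No LD is
    computed here; the mapping is accepted as given.
    """
    mapping = dict(zip(surrogates.iloc[:, 0], surrogates.iloc[:, 1]))
    out = table.copy()
    out["variant_id"] = out["variant_id"].map(lambda v: mapping.get(v, v))
    return out


@dataclass
class HarmonizedInstrumentSet:
    """Per-SNP aligned effect estimates — the unit of all MR computation.

    Attributes
    ----------
    data : pandas.DataFrame
        One row per retained SNP with columns ``variant_id, effect_allele,
        other_allele, eaf, beta_exposure, se_exposure, beta_outcome,
        se_outcome`` plus ``beta_<label>, se_<label>`` per mediator.
    mediators : list of str
        Mediator labels present in ``data``.
    exclusions : pandas.DataFrame
        Columns ``variant_id, reason`` for every dropped SNP.
    annotations : pandas.Series or None
        Optional per-SNP category labels (e.g. DDR / non-DDR), indexed
        like ``data``.
    """

    data: pd.DataFrame
    mediators: list = field(default_factory=list)
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )
    annotations: pd.Series | None = None

    @property
    def n_snps(self) -> int:
        return len(self.data)

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.data["beta_exposure"].to_numpy(float)

    @property
    def se_exposure(self) -> np.ndarray:
        return self.data["se_exposure"].to_numpy(float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.data["beta_outcome"].to_numpy(float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.data["se_outcome"].to_numpy(float)

    def mediator_beta(self, label: str) -> np.ndarray:
        return self.data[f"beta_{label}"].to_numpy(float)

    def mediator_se(self, label: str) -> np.ndarray:
        return self.data[f"se_{label}"].to_numpy(float)

    def subset(self, mask) -> "HarmonizedInstrumentSet":
        """Row subset sharing mediators; exclusion log is not carried over."""
        mask = np.asarray(mask)
        ann = self.annotations[mask].reset_index(drop=True) if self.annotations is not None else None
        return HarmonizedInstrumentSet(
            data=self.data.loc[mask].reset_index(drop=True),
            mediators=list(self.mediators),
            exclusions=pd.DataFrame(columns=["variant_id", "reason"]),
            annotations=ann,
        )

    def drop_variants(self, variant_ids, reason: str) -> "HarmonizedInstrumentSet":
        ids = set(variant_ids)
        keep = ~self.data["variant_id"].isin(ids)
        out = self.subset(keep.to_numpy())
        dropped = pd.DataFrame({"variant_id": sorted(ids), "reason": reason})
        out.exclusions = pd.concat([self.exclusions, dropped], ignore_index=True)
        return out

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def write_exclusions(self, path) -> None:
        self.exclusions.to_csv(path, sep="\t", index=False)


def _align_to(ref: pd.DataFrame, other: pd.DataFrame, window: float):
    """Align ``other`` onto ``ref``'s effect alleles (both indexed by variant_id).

    Returns (beta, se, eaf arrays aligned to ref's allele orientation,
    list of (variant_id, reason) exclusions).
    """
    merged = ref[["variant_id", "effect_allele", "other_allele", "eaf"]].merge(
        other, on="variant_id", suffixes=("_ref", ""), how="inner"
    )
    ea_r = merged["effect_allele_ref"]
    oa_r = merged["other_allele_ref"]
    ea = merged["effect_allele"]
    oa = merged["other_allele"]
    pal = _is_palindromic(ea_r, oa_r)

    same = (ea == ea_r) & (oa == oa_r)
    swapped = (ea == oa_r) & (oa == ea_r)
    # strand flip: compare complemented alleles (non-palindromic only —
    # for palindromic SNPs a strand flip is indistinguishable from a swap)
    ea_c = ea.map(_COMPLEMENT)
    oa_c = oa.map(_COMPLEMENT)
    strand_same = ~pal & (ea_c == ea_r) & (oa_c == oa_r)
    strand_swapped = ~pal & (ea_c == oa_r) & (oa_c == ea_r)

    match = same | strand_same
    flip = (swapped | strand_swapped) & ~match

    beta = merged["beta"].to_numpy(float).copy()
    eaf = merged["eaf"].to_numpy(float).copy()
    se = merged["se"].to_numpy(float).copy()
    beta[flip.to_numpy()] *= -1.0
    eaf[flip.to_numpy()] = 1.0 - eaf[flip.to_numpy()]

    # palindromic, unambiguous by frequency: trust frequency matching over
    # the (strand-unresolvable) allele labels
    amb = pal & (np.abs(merged["eaf_ref"] - 0.5) < window)
    pal_ok = (pal & ~amb & (match | flip)).to_numpy()
    if pal_ok.any():
        ref_eaf = merged["eaf_ref"].to_numpy(float)
        mismatch = pal_ok & (
            np.abs(eaf - ref_eaf) > np.abs((1.0 - eaf) - ref_eaf)
        )
        beta[mismatch] *= -1.0
        eaf[mismatch] = 1.0 - eaf[mismatch]

    excl = []
    for vid in merged.loc[amb, "variant_id"]:
        excl.append((vid, "palindromic_ambiguous"))
    bad = ~(match | flip) & ~amb
    for vid in merged.loc[bad, "variant_id"]:
        excl.append((vid, "allele_mismatch"))

    ok = (match | flip) & ~amb
    return merged["variant_id"], ok.to_numpy(), beta, se, eaf, excl


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    mediators: dict | None = None,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
    orient_exposure_positive: bool = False,
) -> HarmonizedInstrumentSet:
    """Harmonize exposure/outcome (and mediator) tables onto shared alleles.

    All retained SNPs are present in every input table, with all betas
    expressed per copy of the exposure table's effect allele. Where effect
    alleles disagree, outcome/mediator betas are sign-flipped and their eaf
    complemented; A/T and C/G SNPs whose exposure eaf lies within
    ``palindrome_eaf_window`` of 0.5 are excluded as strand-ambiguous;
    palindromic SNPs outside the window are aligned by frequency matching.
    With ``orient_exposure_positive`` the exposure-increasing allele is made
    the effect allele for every SNP (a pure reparameterization; MR
    estimates are invariant to it).
    """
    mediators = mediators or {}
    exposure = validate_assoc_table(exposure, "exposure")
    outcome = validate_assoc_table(outcome, "outcome")
    mediators = {k: validate_assoc_table(v, k) for k, v in mediators.items()}

    excl_records: list[tuple[str, str]] = []

    # drop exposure-side ambiguous palindromes up front
    pal = _is_palindromic(exposure["effect_allele"], exposure["other_allele"])
    amb = pal & ((exposure["eaf"] - 0.5).abs() < palindrome_eaf_window)
    for vid in exposure.loc[amb, "variant_id"]:
        excl_records.append((vid, "palindromic_ambiguous"))
    exposure = exposure.loc[~amb].reset_index(drop=True)

    common = set(exposure["variant_id"]) & set(outcome["variant_id"])
    for med in mediators.values():
        common &= set(med["variant_id"])
    missing = exposure.loc[~exposure["variant_id"].isin(common), "variant_id"]
    for vid in missing:
        excl_records.append((vid, "not_in_all_tables"))
    exposure = exposure.loc[exposure["variant_id"].isin(common)].reset_index(drop=True)

    data = exposure[["variant_id", "chr", "pos", "effect_allele", "other_allele", "eaf"]].copy() \
        if {"chr", "pos"}.issubset(exposure.columns) else \
        exposure[["variant_id", "effect_allele", "other_allele", "eaf"]].copy()
    data["beta_exposure"] = exposure["beta"].to_numpy(float)
    data["se_exposure"] = exposure["se"].to_numpy(float)

    ok_all = np.ones(len(data), dtype=bool)
    aligned_cols = {}
    for label, table in [("outcome", outcome)] + list(mediators.items()):
        vids, ok, beta, se, eaf, excl = _align_to(exposure, table, palindrome_eaf_window)
        assert list(vids) == list(data["variant_id"])
        excl_records.extend(excl)
        ok_all &= ok
        aligned_cols[label] = (beta, se)
    for label, (beta, se) in aligned_cols.items():
        data[f"beta_{label}"] = beta
        data[f"se_{label}"] = se

    data = data.loc[ok_all].reset_index(drop=True)

    if orient_exposure_positive:
        neg = data["beta_exposure"] < 0
        if neg.any():
            ea = data.loc[neg, "effect_allele"].copy()
            data.loc[neg, "effect_allele"] = data.loc[neg, "other_allele"].to_numpy()
            data.loc[neg, "other_allele"] = ea.to_numpy()
            data.loc[neg, "eaf"] = 1.0 - data.loc[neg, "eaf"]
            for col in data.columns:
                if col.startswith("beta_"):
                    data.loc[neg, col] = -data.loc[neg, col]

    data = data.rename(columns={"beta_outcome": "beta_outcome", "se_outcome": "se_outcome"})
    # dedupe exclusion log (a SNP may fail against several tables)
    exclusions = (
        pd.DataFrame(excl_records, columns=["variant_id", "reason"])
        .drop_duplicates(subset="variant_id")
        .reset_index(drop=True)
    )
    return HarmonizedInstrumentSet(
        data=data, mediators=list(mediators), exclusions=exclusions
    )


def read_instrument_set(path, mediators: list | None = None) -> HarmonizedInstrumentSet:
    """Read a harmonized instrument set written by :meth:`HarmonizedInstrumentSet.write`."""
    data = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    if mediators is None:
        mediators = [
            c[len("beta_"):] for c in data.columns
            if c.startswith("beta_") and c not in ("beta_exposure", "beta_outcome")
        ]
    return HarmonizedInstrumentSet(data=data, mediators=mediators)


def subset_by_annotation(iset: HarmonizedInstrumentSet, annotation: pd.DataFrame | None):
    """Partition an instrument set by SNP category (e.g. DDR vs non-DDR).

    ``annotation`` has columns (variant_id, label); retained SNPs without a
    label go to ``"unannotated"``. Conflicting duplicate labels for one SNP
    raise. Returns ``{label: HarmonizedInstrumentSet}`` whose subsets are
    disjoint and union to the input.
    """
    if annotation is None or len(annotation) == 0:
        return {"unannotated": iset.subset(np.ones(iset.n_snps, dtype=bool))}
    ann = annotation.drop_duplicates()
    if ann.iloc[:, 0].duplicated().any():
        dup = ann.loc[ann.iloc[:, 0].duplicated(), ann.columns[0]].iloc[0]
        raise SumstatsError(f"conflicting annotation labels for variant '{dup}'")
    mapping = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
    labels = iset.data["variant_id"].map(lambda v: mapping.get(v, "unannotated"))
    out = {}
    for label in labels.unique():
        sub = iset.subset((labels == label).to_numpy())
        sub.annotations = pd.Series([label] * sub.n_snps)
        out[str(label)] = sub
    return out
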