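"""Reading, writing, validation and allele alignment of GWAS summary statistics.

The on-disk format is a tab-separated table with the fixed column order
``SNP CHR BP A1 A2 FRQ N Z P`` plus a JSON metadata sidecar
(``<path>.meta.json``) carrying trait-level quantities: trait id, binary
flag, sample prevalence, population prevalence and the sum of effective
sample sizes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order of the text format
COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FRQ", "N", "Z", "P"]

_VALID_ALLELES = frozenset("ACGT")
#: strand-ambiguous allele pairs (indistinguishable under strand flip)
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: default header aliases accepted by :func:`read_sumstats`
DEFAULT_ALIASES: Mapping[str, Sequence[str]] = {
    "SNP": ("SNP", "RSID", "ID", "MARKERNAME", "VARIANT_ID"),
    "CHR": ("CHR", "CHROM", "CHROMOSOME"),
    "BP": ("BP", "POS", "POSITION", "BASE_PAIR_LOCATION"),
    "A1": ("A1", "EFFECT_ALLELE", "EA", "ALT"),
    "A2": ("A2", "OTHER_ALLELE", "OA", "NEA", "REF"),
    "FRQ": ("FRQ", "FREQ", "EAF", "MAF", "AF", "A1FREQ"),
    "N": ("N", "NEFF", "OBS_CT", "SAMPLE_SIZE"),
    "Z": ("Z", "ZSCORE", "Z_STAT"),
    "P": ("P", "PVAL", "PVALUE", "P_VALUE"),
    "BETA": ("BETA", "B", "EFFECT", "LOG_ODDS"),
    "SE": ("SE", "STDERR", "STANDARD_ERROR"),
}


@dataclass
class SumStats:
    """Per-variant association results for one trait plus trait metadata.

    ``df`` holds one row per variant with the canonical columns.  For
    binary traits ``sample_prev`` and ``pop_prev`` feed the
    observed-to-liability-scale conversion downstream.
    """

    trait_id: str
    df: pd.DataFrame
    binary: bool = False
    sample_prev: float | None = None
    pop_prev: float | None = None
    n_eff: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"SumStats missing columns: {missing}")
        if self.binary and self.sample_prev is not None:
            if not 0.0 < self.sample_prev < 1.0:
                raise ValueError("sample_prev must lie in (0, 1) for binary traits")

    @property
    def n_variants(self) -> int:
        return len(self.df)

    def metadata(self) -> dict:
        return {
            "trait_id": self.trait_id,
            "binary": self.binary,
            "sample_prev": self.sample_prev,
            "pop_prev": self.pop_prev,
            "n_eff": self.n_eff,
        }

    def copy(self) -> "SumStats":
        return replace(self, df=self.df.copy())


def _resolve_columns(header: Sequence[str], column_map: Mapping[str, str] | None) -> dict:
    """Map canonical names to actual file columns via aliases / explicit map."""
    upper = {h.upper(): h for h in header}
    resolved: dict[str, str] = {}
    explicit = {k.upper(): v for k, v in (column_map or {}).items()}
    for canon, aliases in DEFAULT_ALIASES.items():
        if canon in explicit:
            resolved[canon] = explicit[canon]
            continue
        for alias in aliases:
            if alias in upper:
                resolved[canon] = upper[alias]
                break
    return resolved


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop rows violating the record invariants; return (clean, drop counts)."""
    counts: dict[str, int] = {}

    def _drop(mask: np.ndarray, reason: str, frame: pd.DataFrame) -> pd.DataFrame:
        n_bad = int(mask.sum())
        if n_bad:
            counts[reason] = n_bad
        return frame.loc[~mask]

    df = _drop(df["SNP"].duplicated(keep="first").to_numpy(), "duplicate_id", df)
    alleles_ok = df["A1"].isin(_VALID_ALLELES) & df["A2"].isin(_VALID_ALLELES)
    df = _drop(~alleles_ok.to_numpy(), "invalid_allele", df)
    frq = pd.to_numeric(df["FRQ"], errors="coerce")
    df = _drop(~((frq > 0) & (frq < 1)).to_numpy(), "frequency_out_of_range", df)
    n = pd.to_numeric(df["N"], errors="coerce")
    df = _drop(~(n > 0).to_numpy(), "nonpositive_n", df)
    z = pd.to_numeric(df["Z"], errors="coerce")
    df = _drop(~np.isfinite(z.to_numpy()), "nonfinite_z", df)
    return df, counts


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    **meta,
) -> SumStats:
    """Read and validate a whitespace/tab-delimited summary-statistics file.

    Headers are matched case-insensitively against built-in aliases;
    ``column_map`` overrides (canonical name -> file column).  ``Z`` is
    reconstructed as ``BETA/SE`` when absent, and ``P`` from ``Z`` when
    absent.  Rows failing the invariants are dropped with counts logged.
    Trait metadata is taken from a ``<path>.meta.json`` sidecar when
    present, overridden by keyword arguments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=r"\s+")
    if raw.empty and raw.columns.size == 0:
        raise ValueError(f"{path}: empty file")
    resolved = _resolve_columns(list(raw.columns), column_map)

    out = pd.DataFrame(index=raw.index)
    for canon in ["SNP", "CHR", "BP", "A1", "A2", "FRQ", "N"]:
        if canon not in resolved:
            raise ValueError(f"{path}: cannot resolve mandatory column {canon}")
        out[canon] = raw[resolved[canon]]
    if "Z" in resolved:
        out["Z"] = pd.to_numeric(raw[resolved["Z"]], errors="coerce")
    elif "BETA" in resolved and "SE" in resolved:
        beta = pd.to_numeric(raw[resolved["BETA"]], errors="coerce")
        se = pd.to_numeric(raw[resolved["SE"]], errors="coerce")
        out["Z"] = beta / se
    else:
        raise ValueError(f"{path}: need either a Z column or BETA and SE columns")
    if "P" in resolved:
        out["P"] = pd.to_numeric(raw[resolved["P"]], errors="coerce")
    else:
        out["P"] = 2.0 * stats.norm.sf(np.abs(out["Z"].to_numpy()))

    out["A1"] = out["A1"].astype(str).str.upper()
    out["A2"] = out["A2"].astype(str).str.upper()
    out["SNP"] = out["SNP"].astype(str)
    for col in ("FRQ", "N", "Z", "P"):
        out[col] = pd.to_numeric(out[col], errors="coerce")

    clean, counts = _validate_rows(out)
    if counts:
        logger.warning("%s: dropped rows %s", path, counts)
    if clean.empty and not out.empty:
        raise ValueError(f"{path}: all rows failed validation ({counts})")
    clean = clean.reset_index(drop=True)
    clean["Z"] = clean["Z"] + 0.0  # canonicalize -0.0

    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta_all: dict = {}
    if sidecar.exists():
        meta_all.update(json.loads(sidecar.read_text()))
    meta_all.update({k: v for k, v in meta.items() if v is not None})
    return SumStats(
        trait_id=trait_id or meta_all.get("trait_id", path.stem),
        df=clean[COLUMNS],
        binary=bool(meta_all.get("binary", False)),
        sample_prev=meta_all.get("sample_prev"),
        pop_prev=meta_all.get("pop_prev"),
        n_eff=meta_all.get("n_eff"),
    )


def write_sumstats(s: SumStats, path: str | Path) -> Path:
    """Write the canonical tab-separated table plus the JSON metadata sidecar.

    ``read_sumstats(write_sumstats(s))`` round-trips the structure.
    """
    path = Path(path)
    df = s.df[COLUMNS].copy()
    df["Z"] = df["Z"].astype(float) + 0.0  # -0.0 -> 0.0
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(s.metadata(), indent=1))
    return path


def align_traits(
    traits: Sequence[SumStats],
    drop_ambiguous: bool = False,
) -> list[SumStats]:
    """Restrict traits to shared variants and harmonize alleles to the first trait.

    Per variant, a trait whose ``(A1, A2)`` pair is swapped relative to the
    first trait has its Z negated and its frequency reflected; variants with
    incompatible allele pairs in any trait are dropped, as are
    strand-ambiguous (A/T, C/G) variants when ``drop_ambiguous`` is set.
    Idempotent: aligning aligned traits is the identity.
    """
    if len(traits) < 2:
        raise ValueError("align_traits requires at least two traits")

    shared: pd.Index | None = None
    for t in traits:
        ids = pd.Index(t.df["SNP"])
        shared = ids if shared is None else shared.intersection(ids)
    if shared is None or shared.empty:
        raise ValueError("no variants shared across all traits")

    ref = traits[0].df.set_index("SNP").loc[shared]
    keep = pd.Series(True, index=shared)
    if drop_ambiguous:
        amb = [(a1, a2) in AMBIGUOUS_PAIRS for a1, a2 in zip(ref["A1"], ref["A2"])]
        keep &= ~pd.Series(amb, index=shared)

    frames = [t.df.set_index("SNP").loc[shared] for t in traits]
    flips: list[pd.Series] = []
    n_incompatible = 0
    for frame in frames[1:]:
        same = (frame["A1"] == ref["A1"]) & (frame["A2"] == ref["A2"])
        swapped = (frame["A1"] == ref["A2"]) & (frame["A2"] == ref["A1"])
        bad = ~(same | swapped)
        n_incompatible += int((bad & keep).sum())
        keep &= ~bad
        flips.append(swapped)
    if n_incompatible:
        logger.warning("align_traits: dropped %d variants with incompatible alleles", n_incompatible)
    kept_ids = shared[keep.to_numpy()]
    if kept_ids.empty:
        raise ValueError("alignment left no shared variants")

    out: list[SumStats] = []
    for i, (t, frame) in enumerate(zip(traits, frames)):
        sub = frame.loc[kept_ids].copy()
        if i > 0:
            flip = flips[i - 1].loc[kept_ids].to_numpy()
            sub.loc[flip, "Z"] = -sub.loc[flip, "Z"] + 0.0
            sub.loc[flip, "FRQ"] = 1.0 - sub.loc[flip, "FRQ"]
            sub.loc[flip, ["A1", "A2"]] = sub.loc[flip, ["A2", "A1"]].to_numpy()
        out.append(replace(t, df=sub.reset_index()[COLUMNS]))
    return out
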