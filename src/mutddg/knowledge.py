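"""The statistical flag layer: category probabilities of a mutation causing a
large (|ddG| >= 1 kcal/mol) stability change, the class-imbalance correction,
dataset alteration, regime assignment, curation of experimental tables, and
the side-chain entropy terms.

Four flags describe a mutation: the wild-type residue type P(X->any), the
mutant residue type P(any->Y), the burial-pair of the site P(loc), and the
SSE-pair P(SSE).  Each probability is the fraction of database cases in that
category with a large effect, corrected for the overall large/small imbalance
(P = Mlarge/M * (1 + dN), dN = Mlarge_total/Msmall_total - 1).  Altered
probabilities P' are re-estimated after rescaling each |ddG| by the other
three flags' probabilities; their mean selects the small- or large-effect
scoring model (large iff P >= 0.5).

Labeled datasets are pandas DataFrames with columns
protein, chain, position, wt, mt, ddg, ph, loc_code, sse_code[, source].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .descriptors import residue_sasa, load_reference_sasa
from .residues import AA3_TO_1, as_three_letter, load_rotamer_counts
from .structure import ProteinStructure

logger = logging.getLogger(__name__)

DDG_CUTOFF = 1.0   # kcal/mol: |ddG| at or above this is a "large" effect
MIN_COUNT = 5      # categories with fewer cases get probability 0.5

REQUIRED_COLUMNS = ("protein", "chain", "position", "wt", "mt", "ddg", "ph")


@dataclass
class ProbabilityTables:
    """Per-category flag probabilities, raw (P) and altered (P')."""

    p_wt: Dict[str, float]
    p_mt: Dict[str, float]
    p_loc: Dict[str, float]
    p_sse: Dict[str, float]
    pprime_wt: Dict[str, float]
    pprime_mt: Dict[str, float]
    pprime_loc: Dict[str, float]
    pprime_sse: Dict[str, float]
    counts_wt: Dict[str, int] = field(default_factory=dict)
    counts_mt: Dict[str, int] = field(default_factory=dict)
    counts_loc: Dict[str, int] = field(default_factory=dict)
    counts_sse: Dict[str, int] = field(default_factory=dict)
    delta_n: float = 0.0
    cutoff: float = DDG_CUTOFF
    min_count: int = MIN_COUNT


@dataclass(frozen=True)
class FlagProbabilities:
    p_wt: float    # P(X->any)
    p_mt: float    # P(any->Y)
    p_loc: float
    p_sse: float

    @property
    def combined(self) -> float:
        return (self.p_wt + self.p_mt + self.p_loc + self.p_sse) / 4.0

    @property
    def regime(self) -> str:
        return "large" if self.combined >= 0.5 else "small"


def load_default_tables() -> ProbabilityTables:
    """The bundled probability tables (and their published dN = 0.069)."""
    wt_mt = pd.read_csv(
        resources.files("mutddg") / "data" / "prob_wt_mt.tsv", sep="\t"
    )
    loc_sse = pd.read_csv(
        resources.files("mutddg") / "data" / "prob_loc_sse.tsv", sep="\t"
    )
    loc = loc_sse[loc_sse["kind"] == "loc"]
    sse = loc_sse[loc_sse["kind"] == "sse"]
    return ProbabilityTables(
        p_wt=dict(zip(wt_mt["aa"], wt_mt["p_wt"])),
        p_mt=dict(zip(wt_mt["aa"], wt_mt["p_mt"])),
        p_loc=dict(zip(loc["code"], loc["p"])),
        p_sse=dict(zip(sse["code"], sse["p"])),
        pprime_wt=dict(zip(wt_mt["aa"], wt_mt["pprime_wt"])),
        pprime_mt=dict(zip(wt_mt["aa"], wt_mt["pprime_mt"])),
        pprime_loc=dict(zip(loc["code"], loc["pprime"])),
        pprime_sse=dict(zip(sse["code"], sse["pprime"])),
        counts_wt=dict(zip(wt_mt["aa"], wt_mt["wt_cases"])),
        counts_mt=dict(zip(wt_mt["aa"], wt_mt["mt_cases"])),
        counts_loc=dict(zip(loc["code"], loc["cases"])),
        counts_sse=dict(zip(sse["code"], sse["cases"])),
        delta_n=0.069,
    )


def curate_dataset(raw: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Clean an experimental table.  In order: drop exact duplicates; drop
    entries at pH < 5 or > 9; for repeated (protein, mutation) measurements
    fuse to the mean when the spread is < 0.1 kcal/mol, otherwise drop the
    whole group.  Returns (curated table, audit counts)."""
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"missing required column {col!r}")
    audit: Dict[str, int] = {"input": len(raw)}

    df = raw.drop_duplicates()
    audit["duplicates_removed"] = len(raw) - len(df)

    kept = df[(df["ph"] >= 5.0) & (df["ph"] <= 9.0)]
    audit["ph_removed"] = len(df) - len(kept)
    df = kept

    keys = ["protein", "chain", "position", "wt", "mt"]
    fused_rows = []
    fused = dropped = 0
    for _, grp in df.groupby(keys, sort=False):
        if len(grp) == 1:
            fused_rows.append(grp)
            continue
        spread = grp["ddg"].max() - grp["ddg"].min()
        if spread < 0.1:
            row = grp.iloc[[0]].copy()
            row["ddg"] = grp["ddg"].mean()
            fused_rows.append(row)
            fused += len(grp) - 1
        else:
            dropped += len(grp)
    audit["fused_away"] = fused
    audit["inconsistent_removed"] = dropped
    out = (
        pd.concat(fused_rows, ignore_index=True)
        if fused_rows
        else df.iloc[0:0].copy()
    )
    audit["output"] = len(out)
    for rule, count in audit.items():
        logger.info("curation %s: %d", rule, count)
    return out, audit


def compute_delta_n(ddg: Iterable[float], cutoff: float = DDG_CUTOFF) -> float:
    """Class-imbalance correction dN = n_large/n_small - 1."""
    vals = np.abs(np.asarray(list(ddg), float))
    if len(vals) == 0:
        raise ValueError("empty dataset")
    n_large = int(np.sum(vals >= cutoff))
    n_small = len(vals) - n_large
    if n_large == 0 or n_small == 0:
        raise ValueError("one of the large/small subsets is empty")
    return n_large / n_small - 1.0


def estimate_probability(
    m_large: int,
    m_total: int,
    delta_n: float = 0.0,
    min_count: int = MIN_COUNT,
) -> float:
    """P = Mlarge/M * (1 + dN), clipped to [0, 1]; sparse categories
    (M < min_count) get the uninformative 0.5."""
    if m_total < 0 or not 0 <= m_large <= m_total:
        raise ValueError("require 0 <= m_large <= m_total")
    if m_total < min_count:
        return 0.5
    return float(np.clip(m_large / m_total * (1.0 + delta_n), 0.0, 1.0))


def alter_ddg(ddg_abs: float, other_probs: Sequence[float]) -> float:
    """Rescale |ddG| by the other flags' probabilities:
    (2/3) sum P_j |ddG| below the cutoff, (2/3) sum (1-P_j) |ddG| at/above."""
    if ddg_abs < 0:
        raise ValueError("ddg_abs must be non-negative")
    probs = list(other_probs)
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    if ddg_abs < DDG_CUTOFF:
        return (2.0 / 3.0) * sum(probs) * ddg_abs
    return (2.0 / 3.0) * sum(1.0 - p for p in probs) * ddg_abs


_FLAG_COLUMNS = {"wt": "wt", "mt": "mt", "loc": "loc_code", "sse": "sse_code"}


def _raw_probs(
    df: pd.DataFrame,
    ddg_abs: np.ndarray,
    delta_n: float,
    cutoff: float,
    min_count: int,
) -> Dict[str, Dict[str, float]]:
    large = ddg_abs >= cutoff
    out: Dict[str, Dict[str, float]] = {}
    for flag, col in _FLAG_COLUMNS.items():
        probs: Dict[str, float] = {}
        for cat, idx in df.groupby(col, sort=True).groups.items():
            m = len(idx)
            ml = int(large[df.index.get_indexer(idx)].sum())
            probs[cat] = estimate_probability(ml, m, delta_n, min_count)
        out[flag] = probs
    return out


def build_tables(
    dataset: pd.DataFrame,
    cutoff: float = DDG_CUTOFF,
    min_count: int = MIN_COUNT,
) -> ProbabilityTables:
    """Estimate raw flag probabilities, perform one alteration pass, and
    re-estimate the altered probabilities P'."""
    df = dataset.reset_index(drop=True)
    ddg_abs = np.abs(df["ddg"].to_numpy(float))
    delta_n = compute_delta_n(ddg_abs, cutoff)
    raw = _raw_probs(df, ddg_abs, delta_n, cutoff, min_count)

    flags = list(_FLAG_COLUMNS)
    prime: Dict[str, Dict[str, float]] = {}
    for flag in flags:
        others = [f for f in flags if f != flag]
        other_p = np.ones((len(df), len(others)))
        for k, f in enumerate(others):
            col = _FLAG_COLUMNS[f]
            other_p[:, k] = df[col].map(raw[f]).to_numpy(float)
        small = ddg_abs < cutoff
        altered = np.where(
            small,
            (2.0 / 3.0) * other_p.sum(axis=1) * ddg_abs,
            (2.0 / 3.0) * (3.0 - other_p.sum(axis=1)) * ddg_abs,
        )
        try:
            dn_alt = compute_delta_n(altered, cutoff)
        except ValueError:
            dn_alt = 0.0
        large_alt = altered >= cutoff
        probs: Dict[str, float] = {}
        col = _FLAG_COLUMNS[flag]
        for cat, idx in df.groupby(col, sort=True).groups.items():
            rows = df.index.get_indexer(idx)
            probs[cat] = estimate_probability(
                int(large_alt[rows].sum()), len(rows), dn_alt, min_count
            )
        prime[flag] = probs

    counts = {
        flag: df[_FLAG_COLUMNS[flag]].value_counts().to_dict() for flag in flags
    }
    return ProbabilityTables(
        p_wt=raw["wt"], p_mt=raw["mt"], p_loc=raw["loc"], p_sse=raw["sse"],
        pprime_wt=prime["wt"], pprime_mt=prime["mt"],
        pprime_loc=prime["loc"], pprime_sse=prime["sse"],
        counts_wt=counts["wt"], counts_mt=counts["mt"],
        counts_loc=counts["loc"], counts_sse=counts["sse"],
        delta_n=delta_n, cutoff=cutoff, min_count=min_count,
    )


def _lookup(table: Dict[str, float], code: str, what: str) -> float:
    if code not in table:
        logger.warning("unknown %s category %r; using probability 0.5", what, code)
        return 0.5
    return float(table[code])


def lookup_flags(
    wt_aa: str,
    mt_aa: str,
    loc_code: str,
    sse_code: str,
    tables: ProbabilityTables | None = None,
    use_prime: bool = True,
) -> FlagProbabilities:
    """The four flag probabilities (altered P' by default) for a mutation."""
    tables = tables or load_default_tables()
    wt1 = AA3_TO_1.get(as_three_letter(wt_aa))
    mt1 = AA3_TO_1.get(as_three_letter(mt_aa))
    if use_prime:
        src = (tables.pprime_wt, tables.pprime_mt, tables.pprime_loc, tables.pprime_sse)
    else:
        src = (tables.p_wt, tables.p_mt, tables.p_loc, tables.p_sse)
    return FlagProbabilities(
        p_wt=_lookup(src[0], wt1, "WT residue"),
        p_mt=_lookup(src[1], mt1, "MT residue"),
        p_loc=_lookup(src[2], loc_code, "location pair"),
        p_sse=_lookup(src[3], sse_code, "SSE pair"),
    )


# ---------------------------------------------------------------------------
# side-chain entropy

def side_chain_entropy(rsasa: float, n_rotamers: int) -> float:
    """S = ln[rSASA (R - 1) + 1]: 0 when buried, ln R when fully exposed."""
    if n_rotamers < 1:
        raise ValueError("rotamer count must be >= 1")
    r = float(np.clip(rsasa, 0.0, 1.0))
    return math.log(r * (n_rotamers - 1) + 1.0)


def entropy_sum(
    structure: ProteinStructure,
    rotamer_counts: Dict[str, int] | None = None,
    params=None,
) -> float:
    """Ssum: side-chain entropies summed over all residues."""
    rotamer_counts = rotamer_counts or load_rotamer_counts()
    per_res = residue_sasa(structure, params)
    ref = load_reference_sasa()
    total = 0.0
    for rid, _ in structure.residues():
        rsasa = per_res[rid.key()] / ref[rid.aa]
        total += side_chain_entropy(rsasa, rotamer_counts[rid.aa])
    return total


def site_entropy(
    structure: ProteinStructure,
    chain: str,
    seq: int,
    icode: str = "",
    rotamer_counts: Dict[str, int] | None = None,
    params=None,
) -> float:
    """Side-chain entropy of a single residue."""
    rotamer_counts = rotamer_counts or load_rotamer_counts()
    rid, _ = structure.residue(chain, seq, icode)
    per_res = residue_sasa(structure, params)
    rsasa = per_res[rid.key()] / load_reference_sasa()[rid.aa]
    return side_chain_entropy(rsasa, rotamer_counts[rid.aa])
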