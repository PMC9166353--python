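"""Pairwise dN/dS filtering and aggregation, a Nei-Gojobori counting
estimator for self-contained testing, and the genome-selection filter.

The filtering rules follow the divergence protocol exactly as stated:
pairs with dS > 1.5 (saturation), dS < 0.1 (same-population pairs) or
omega > 10 (artifacts) are removed — strict inequalities, so boundary
values survive. Genomes with fewer than 25 surviving estimates are
discarded, applied once (no iterative re-pruning). The per-genus median
of the surviving omegas is attached to the genus representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

__all__ = [
    "PAIR_COLUMNS",
    "filter_pairwise",
    "genome_min_support",
    "median_dnds",
    "ng86_dnds",
    "select_genomes",
    "read_pairs",
    "read_metadata",
    "SaturationError",
]

PAIR_COLUMNS = ["genus", "genome_a", "genome_b", "dN", "dS", "omega"]
META_COLUMNS = ["accession", "genus", "class", "phylum", "completeness", "contamination", "is_cpr"]

DS_MAX = 1.5
DS_MIN = 0.1
OMEGA_MAX = 10.0
MIN_ESTIMATES = 25


class SaturationError(ValueError):
    """Proportion of differences >= 3/4: Jukes-Cantor correction undefined."""


def read_pairs(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    return df


def read_metadata(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Filtering and aggregation
# ---------------------------------------------------------------------------

def filter_pairwise(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the three divergence filters in order; return survivors + log.

    Rules (strict inequalities; boundary values kept):
      1. dS > 1.5  -> saturation
      2. dS < 0.1  -> same-population pair
      3. omega > 10 -> artifact
    """
    if (table["dN"] < 0).any() or (table["dS"] < 0).any():
        raise ValueError("negative dN or dS in pairwise table")
    kept = table
    log: dict[str, int] = {"input": len(table)}
    m = kept["dS"] > DS_MAX
    log["removed_ds_saturated"] = int(m.sum())
    kept = kept[~m]
    m = kept["dS"] < DS_MIN
    log["removed_ds_too_low"] = int(m.sum())
    kept = kept[~m]
    m = kept["omega"] > OMEGA_MAX
    log["removed_omega_artifact"] = int(m.sum())
    kept = kept[~m]
    log["kept"] = len(kept)
    return kept.reset_index(drop=True), log


def genome_min_support(
    kept: pd.DataFrame, min_estimates: int = MIN_ESTIMATES
) -> tuple[set[str], pd.DataFrame]:
    """Genomes appearing in >= ``min_estimates`` surviving pairs.

    Applied once: support is counted on the input table, and pairs touching
    a discarded genome are then dropped without re-checking the survivors
    (the cascade is logged instead).
    """
    counts: dict[str, int] = {}
    for col in ("genome_a", "genome_b"):
        for g, c in kept[col].value_counts().items():
            counts[g] = counts.get(g, 0) + int(c)
    retained = {g for g, c in counts.items() if c >= min_estimates}
    surviving = kept[
        kept["genome_a"].isin(retained) & kept["genome_b"].isin(retained)
    ].reset_index(drop=True)
    cascade = {
        g
        for col in ("genome_a", "genome_b")
        for g, c in surviving[col].value_counts().items()
        if c < min_estimates
    }
    if cascade:
        logger.info(
            "%d retained genomes fell below %d estimates after pair removal "
            "(no re-pruning applied)",
            len(cascade),
            min_estimates,
        )
    return retained, surviving


def median_dnds(
    kept: pd.DataFrame, representatives: dict[str, str] | pd.Series
) -> pd.Series:
    """Per-genus median omega over surviving pairs, attached to the genus
    representative's tip label. Even counts use the midpoint convention."""
    if isinstance(representatives, pd.Series):
        representatives = representatives.to_dict()
    med = kept.groupby("genus")["omega"].median()
    out = {}
    for genus, value in med.items():
        rep = representatives.get(genus)
        if rep is None:
            logger.info("genus %s has no representative; median dropped", genus)
            continue
        out[rep] = float(value)
    return pd.Series(out, name="dnds_median", dtype=float)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) counting estimator with Jukes-Cantor correction
# ---------------------------------------------------------------------------

_CODE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CODE.stop_codons)
_NUCS = "ACGT"


def _aa(codon: str) -> str | None:
    return None if codon in _STOPS else _CODE.forward_table[codon]


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes s/3 synonymous sites where s of its three
    possible substitutions are synonymous; changes creating a stop codon
    count as nonsynonymous.
    """
    syn = 0.0
    for pos in range(3):
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in _STOPS and _aa(alt) == _aa(codon):
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Multi-position differences are averaged over all substitution orderings;
    pathways passing through a stop codon are excluded when any stop-free
    pathway exists.
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        cur = c1
        syn = nonsyn = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            if not blocked and _aa(nxt) == _aa(cur):
                syn += 1.0
            elif not blocked:
                nonsyn += 1.0
            cur = nxt
        paths.append((blocked, syn, nonsyn))
    open_paths = [p for p in paths if not p[0]]
    if open_paths:
        use = open_paths
    else:  # all pathways blocked: fall back to counting every step, stops nonsyn
        use = []
        for order in permutations(positions):
            cur = c1
            syn = nonsyn = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt not in _STOPS and cur not in _STOPS and _aa(nxt) == _aa(cur):
                    syn += 1.0
                else:
                    nonsyn += 1.0
                cur = nxt
            use.append((True, syn, nonsyn))
    s = float(np.mean([p[1] for p in use]))
    return s, len(positions) - s


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(
            f"proportion of differences {p:.3f} >= 3/4; distance undefined"
        )
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def _validate_codon_seq(seq: str, name: str) -> None:
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
    if set(seq) - set(_NUCS):
        bad = sorted(set(seq) - set(_NUCS))
        raise ValueError(f"{name}: non-ACGT characters {bad} (ambiguity not resolved)")
    for i in range(0, len(seq), 3):
        if seq[i : i + 3] in _STOPS:
            raise ValueError(f"{name}: internal stop codon at position {i}")


def ng86_dnds(seq1: str, seq2: str) -> dict[str, float]:
    """Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction.

    Returns a dict with site counts (S, N), difference counts (Sd, Nd),
    proportions (pS, pN), corrected distances (dN, dS) and omega. Identical
    sequences yield dN = dS = 0 with ``omega_defined`` False.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    _validate_codon_seq(seq1, "seq1")
    _validate_codon_seq(seq2, "seq2")

    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _codon_diffs(c1, c2)
        Sd += sd
        Nd += nd

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    defined = dS > 0
    return {
        "S": S,
        "N": N,
        "Sd": Sd,
        "Nd": Nd,
        "pS": pS,
        "pN": pN,
        "dS": dS,
        "dN": dN,
        "omega": dN / dS if defined else np.nan,
        "omega_defined": defined,
    }


# ---------------------------------------------------------------------------
# Genome selection
# ---------------------------------------------------------------------------

def select_genomes(
    metadata: pd.DataFrame,
    seed: int,
    completeness_min: float = 95.0,
    cpr_completeness_min: float = 80.0,
    contamination_max: float = 5.0,
    class_cap: int = 500,
    min_genus_size: int = 2,
) -> tuple[set[str], dict[str, int]]:
    """Quality filter, class-level downsampling, and genus-size filter.

    Rules in order, inclusive thresholds:
      1. completeness >= 95 and contamination <= 5 (CPR: completeness >= 80);
      2. classes with more than ``class_cap`` genomes are randomly
         downsampled to ``class_cap`` (seeded, without replacement);
      3. genera with fewer than ``min_genus_size`` genomes are discarded.
    """
    bad = metadata[
        (metadata["completeness"] < 0)
        | (metadata["completeness"] > 100)
        | (metadata["contamination"] < 0)
    ]
    if len(bad):
        raise ValueError(f"{len(bad)} metadata rows violate completeness/contamination bounds")

    counts: dict[str, int] = {"input": len(metadata)}
    need = np.where(
        metadata["is_cpr"].astype(bool), cpr_completeness_min, completeness_min
    )
    quality = metadata[
        (metadata["completeness"] >= need)
        & (metadata["contamination"] <= contamination_max)
    ]
    counts["after_quality"] = len(quality)

    rng = np.random.default_rng(seed)
    parts = []
    # iterate classes in sorted order so downsampling is seed-reproducible
    for cls in sorted(quality["class"].unique()):
        sub = quality[quality["class"] == cls]
        if len(sub) > class_cap:
            idx = rng.choice(len(sub), size=class_cap, replace=False)
            sub = sub.iloc[np.sort(idx)]
        parts.append(sub)
    sampled = pd.concat(parts) if parts else quality.iloc[:0]
    counts["after_downsampling"] = len(sampled)

    genus_sizes = sampled["genus"].value_counts()
    keep_genera = set(genus_sizes[genus_sizes >= min_genus_size].index)
    final = sampled[sampled["genus"].isin(keep_genera)]
    counts["after_genus_filter"] = len(final)
    counts["n_genera"] = final["genus"].nunique()
    return set(final["accession"]), counts
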