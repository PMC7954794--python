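"""Deep-mutational-scanning scores from variant count tables.

The saturation library mutates each codon of a 58-residue SH3 domain to all
64 codons; pooled selection couples variant fitness (here, interaction
strength in a complementation assay) to variant frequency. Scoring chain:

1. per-position variant frequencies: (count + pseudocount) / depth, with the
   0.5 pseudocount applied at the count level;
2. pseudolog2 ratio of selection over reference frequency;
3. DMS score: ratio minus the median ratio of synonymous codon substitutions
   (codon changes that preserve the WT amino acid), computed per replicate
   and then averaged across biological replicates;
4. classification against the synonymous score distribution: below its 1st
   percentile -> deleterious, above the 99th -> improving, else neutral;
5. amino-acid-level aggregation (mean over codons encoding a substitution)
   and the four-way two-interaction category assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
CODON_TO_AA = {c: str(Seq(c).translate()) for c in CODONS}

Variant = tuple[int, str]  # (1-based position, codon)


@dataclass
class DMSCountTable:
    """Variant counts for one condition and replicate.

    `counts` maps (position, codon) -> reads; `depth` maps position -> total
    reads at that position; `wt_codons` gives the reference codon per
    position (1-based, contiguous).
    """

    condition: str  # "reference" | "selection"
    replicate: int
    counts: dict[Variant, int]
    depth: dict[int, int]
    wt_codons: dict[int, str]

    def positions(self) -> list[int]:
        return sorted(self.depth)


@dataclass(frozen=True)
class VariantScore:
    position: int
    codon: str
    aa: str
    wt_aa: str
    is_synonymous: bool
    ratio: float
    dms_score: float
    variant_class: str = "unclassified"


def variant_frequencies(
    table: DMSCountTable, pseudocount: float = 0.5
) -> dict[Variant, float]:
    """Depth-normalized variant frequencies with a count-level pseudocount."""
    freqs: dict[Variant, float] = {}
    for pos in table.positions():
        d = table.depth[pos]
        if d <= 0:
            warnings.warn(f"position {pos}: zero depth, skipped")
            continue
        for codon in CODONS:
            count = table.counts.get((pos, codon), 0)
            freqs[(pos, codon)] = (count + pseudocount) / d
    return freqs


def variant_log_ratios(
    sel_freq: Mapping[Variant, float], ref_freq: Mapping[Variant, float]
) -> dict[Variant, float]:
    """log2 of selection over reference frequency, per variant.

    Variants present on one side only are treated as count 0 there, which the
    pseudocount already makes finite.
    """
    out: dict[Variant, float] = {}
    for key in set(sel_freq) | set(ref_freq):
        s, r = sel_freq.get(key), ref_freq.get(key)
        if s is None or r is None:
            continue  # position missing entirely on one side
        out[key] = float(np.log2(s / r))
    return out


def synonymous_variants(wt_codons: Mapping[int, str]) -> set[Variant]:
    """Codon substitutions that preserve the WT amino acid (WT codon excluded)."""
    out: set[Variant] = set()
    for pos, wt in wt_codons.items():
        aa = CODON_TO_AA[wt]
        for codon in CODONS:
            if codon != wt and CODON_TO_AA[codon] == aa:
                out.add((pos, codon))
    return out


def dms_scores(
    ratios_by_replicate: Sequence[Mapping[Variant, float]],
    wt_codons: Mapping[int, str],
) -> list[VariantScore]:
    """Synonymous-scaled DMS scores, averaged over replicates.

    Each replicate's ratios are shifted by the median ratio of its synonymous
    substitutions, the per-variant scores are averaged across replicates, and
    the averaged scores are re-centered on their synonymous median so the
    synonymous median is exactly 0 by construction (averaging two
    individually centered replicates leaves a residual of order the sampling
    noise; the re-centering removes it).
    """
    syn = synonymous_variants(wt_codons)
    scaled: list[dict[Variant, float]] = []
    for ratios in ratios_by_replicate:
        syn_vals = [v for k, v in ratios.items() if k in syn]
        if len(syn_vals) < 2:
            raise ValueError("need at least two synonymous variants to scale")
        med = float(np.median(syn_vals))
        scaled.append({k: v - med for k, v in ratios.items()})
    common = set(scaled[0])
    for s in scaled[1:]:
        common &= set(s)
    averaged = {k: float(np.mean([s[k] for s in scaled])) for k in common}
    syn_avg = [v for k, v in averaged.items()
               if k in syn and k[1] != wt_codons[k[0]]]
    recenter = float(np.median(syn_avg)) if syn_avg else 0.0
    out: list[VariantScore] = []
    for pos, codon in sorted(common):
        wt = wt_codons[pos]
        if codon == wt:
            continue
        avg_score = averaged[(pos, codon)] - recenter
        avg_ratio = float(np.mean([r[(pos, codon)] for r in ratios_by_replicate]))
        aa = CODON_TO_AA[codon]
        out.append(
            VariantScore(
                position=pos, codon=codon, aa=aa, wt_aa=CODON_TO_AA[wt],
                is_synonymous=(pos, codon) in syn,
                ratio=avg_ratio, dms_score=avg_score,
            )
        )
    return out


def classify_variants(
    scores: Sequence[VariantScore], pct_low: float = 1.0, pct_high: float = 99.0
) -> list[VariantScore]:
    """Classify against the synonymous score distribution (codon level).

    Strictly below its `pct_low` percentile -> deleterious; strictly above
    the `pct_high` percentile -> improving; otherwise neutral. Percentiles
    use linear interpolation.
    """
    syn_scores = np.array([s.dms_score for s in scores if s.is_synonymous])
    if syn_scores.size == 0:
        raise ValueError("no synonymous variants available for classification")
    if syn_scores.size < 20:
        warnings.warn(
            f"only {syn_scores.size} synonymous variants: percentile thresholds unstable"
        )
    lo = float(np.percentile(syn_scores, pct_low))
    hi = float(np.percentile(syn_scores, pct_high))
    out = []
    for s in scores:
        if s.dms_score < lo:
            cls = "deleterious"
        elif s.dms_score > hi:
            cls = "improving"
        else:
            cls = "neutral"
        out.append(
            VariantScore(
                position=s.position, codon=s.codon, aa=s.aa, wt_aa=s.wt_aa,
                is_synonymous=s.is_synonymous, ratio=s.ratio,
                dms_score=s.dms_score, variant_class=cls,
            )
        )
    return out


def aggregate_to_aa(
    scores: Sequence[VariantScore], include_stops: bool = False
) -> pd.DataFrame:
    """Amino-acid-level scores: mean over codons encoding each substitution.

    The WT codon is never included; synonymous codon substitutions aggregate
    to the WT amino acid. Stop-codon variants are reported separately unless
    `include_stops` is set.
    """
    rows = []
    for s in scores:
        if s.aa == "*" and not include_stops:
            continue
        rows.append({"position": s.position, "aa": s.aa, "dms_score": s.dms_score})
    df = pd.DataFrame(rows)
    return (
        df.groupby(["position", "aa"], as_index=False)["dms_score"]
        .mean()
        .sort_values(["position", "aa"])
        .reset_index(drop=True)
    )


def aa_matrix(aa_scores: pd.DataFrame) -> pd.DataFrame:
    """Wide heatmap-ready matrix: positions x amino acids."""
    return aa_scores.pivot(index="aa", columns="position", values="dms_score")


@dataclass(frozen=True)
class MutantCategory:
    position: int
    aa: str
    category: str  # destabilize_both | destabilize_ppi1_only | destabilize_ppi2_only | neutral_or_increasing


def assign_categories(
    aa_scores_ppi1: pd.DataFrame,
    aa_scores_ppi2: pd.DataFrame,
    threshold_ppi1: float,
    threshold_ppi2: float,
) -> list[MutantCategory]:
    """Four-way category per substitution from two interactions' scores.

    A substitution destabilizes an interaction when its aa-level score falls
    strictly below that interaction's own synonymous 1st-percentile
    threshold. Substitutions scored in only one interaction are excluded.
    """
    m1 = aa_scores_ppi1.set_index(["position", "aa"])["dms_score"]
    m2 = aa_scores_ppi2.set_index(["position", "aa"])["dms_score"]
    common = m1.index.intersection(m2.index)
    dropped = len(m1.index.symmetric_difference(m2.index))
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "%d substitutions scored in only one interaction excluded", dropped
        )
    out = []
    for pos, aa in sorted(common):
        d1 = m1.loc[(pos, aa)] < threshold_ppi1
        d2 = m2.loc[(pos, aa)] < threshold_ppi2
        if d1 and d2:
            cat = "destabilize_both"
        elif d1:
            cat = "destabilize_ppi1_only"
        elif d2:
            cat = "destabilize_ppi2_only"
        else:
            cat = "neutral_or_increasing"
        out.append(MutantCategory(position=pos, aa=aa, category=cat))
    return out


def synonymous_threshold(scores: Sequence[VariantScore], pct: float = 1.0) -> float:
    """Percentile of the codon-level synonymous score distribution."""
    syn = np.array([s.dms_score for s in scores if s.is_synonymous])
    if syn.size == 0:
        raise ValueError("no synonymous variants")
    return float(np.percentile(syn, pct))


def scores_frame(scores: Sequence[VariantScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"position": s.position, "codon": s.codon, "aa": s.aa,
             "wt_aa": s.wt_aa, "is_synonymous": s.is_synonymous,
             "ratio": s.ratio, "dms_score": s.dms_score,
             "class": s.variant_class}
            for s in scores
        ]
    )


def read_count_tables(path: str) -> list[DMSCountTable]:
    """Read count tables from a long TSV: condition, replicate, position,
    codon, count, depth, wt_codon."""
    df = pd.read_csv(path, sep="\t")
    tables = []
    for (cond, rep), sub in df.groupby(["condition", "replicate"]):
        counts = {(int(r.position), r.codon): int(r.count)
                  for r in sub.itertuples()}
        depth = sub.groupby("position")["depth"].first().astype(int).to_dict()
        wt = sub.groupby("position")["wt_codon"].first().to_dict()
        tables.append(DMSCountTable(condition=cond, replicate=int(rep),
                                    counts=counts, depth=depth, wt_codons=wt))
    return tables


def write_count_tables(tables: Sequence[DMSCountTable], path: str) -> None:
    rows = []
    for t in tables:
        for (pos, codon), count in sorted(t.counts.items()):
            rows.append({"condition": t.condition, "replicate": t.replicate,
                         "position": pos, "codon": codon, "count": count,
                         "depth": t.depth[pos], "wt_codon": t.wt_codons[pos]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
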