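"""Species-level refinement of genus-only ASVs from BLAST hits.

DADA2 assigns species only on exact sequence matches, which leaves many
ASVs with a genus but no species.  This module applies a conservative
alignment-based rule to fill those in: among hits with >= 95% identity and
100% query coverage, the best hit's species is adopted only when its
identity is at least 97% and it beats the best *different-species* hit by
more than two identity percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import BlastHitTable, FormatError, TaxonomyTable


@dataclass(frozen=True)
class RefinementParams:
    """Thresholds of the assignment rule (identity/coverage in percent)."""

    min_identity: float = 95.0
    min_coverage: float = 100.0
    min_best_identity: float = 97.0
    min_gap: float = 2.0
    # gap against the best hit of a different species (default) or the
    # literal second-ranked alignment
    gap_vs_second_alignment: bool = False

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage", "min_best_identity"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise FormatError(f"{name} must be within [0, 100], got {v}")
        if self.min_best_identity < self.min_identity:
            raise FormatError("min_best_identity must be >= min_identity")
        if self.min_gap < 0:
            raise FormatError("min_gap must be non-negative")


@dataclass
class RefinementRecord:
    taxon_id: str
    outcome: str  # assigned | no_hits | prefilter | best_below_min | gap_too_small
    species: str | None = None
    best_identity: float | None = None
    runner_up_identity: float | None = None


def _rank_key(row) -> tuple:
    # identity desc, bitscore desc, subject id lexicographic
    return (-row.percent_identity, -row.bitscore, row.subject_id)


def refine_one(hits: pd.DataFrame, params: RefinementParams) -> RefinementRecord:
    """Apply the rule to one candidate's hit set (taxon_id left blank)."""
    rec = RefinementRecord(taxon_id="", outcome="no_hits")
    if hits.empty:
        return rec
    cov = hits["percent_query_coverage"].round(1)
    passing = hits[(hits["percent_identity"] >= params.min_identity)
                   & (cov >= params.min_coverage)]
    if passing.empty:
        rec.outcome = "prefilter"
        return rec
    ranked = sorted(passing.itertuples(index=False), key=_rank_key)
    best = ranked[0]
    rec.best_identity = best.percent_identity
    if best.percent_identity < params.min_best_identity:
        rec.outcome = "best_below_min"
        return rec
    if params.gap_vs_second_alignment:
        runner = ranked[1] if len(ranked) > 1 else None
    else:
        runner = next(
            (h for h in ranked[1:] if h.subject_species != best.subject_species),
            None,
        )
    if runner is not None:
        rec.runner_up_identity = runner.percent_identity
        if best.percent_identity - runner.percent_identity <= params.min_gap:
            rec.outcome = "gap_too_small"
            return rec
    rec.outcome = "assigned"
    rec.species = best.subject_species
    return rec


def refine_species(taxonomy: TaxonomyTable, hits: BlastHitTable,
                   params: RefinementParams = RefinementParams()
                   ) -> tuple[TaxonomyTable, pd.DataFrame]:
    """Assign species to genus-only taxa where the hit evidence allows it.

    Returns a new TaxonomyTable (the input is never mutated) and a log
    DataFrame with one row per candidate recording outcome and evidence.
    Rows that already carry a species are untouched.
    """
    unknown = set(hits.df["query_id"]) - set(taxonomy.df.index)
    if unknown:
        raise FormatError(
            f"hits reference taxa absent from taxonomy: {', '.join(sorted(unknown)[:5])}"
        )
    refined = taxonomy.df.copy()
    records: list[RefinementRecord] = []
    for taxon_id in taxonomy.candidates_for_species_refinement():
        rec = refine_one(hits.hits_for(taxon_id), params)
        rec.taxon_id = taxon_id
        records.append(rec)
        if rec.outcome == "assigned":
            refined.loc[taxon_id, "species"] = rec.species
    log = pd.DataFrame(
        [(r.taxon_id, r.outcome, r.species, r.best_identity, r.runner_up_identity)
         for r in records],
        columns=["taxon_id", "outcome", "species",
                 "best_identity", "runner_up_identity"],
    )
    return TaxonomyTable(refined), log
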