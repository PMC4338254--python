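"""Marker-validation reporting: banding to genotype calls to concordance.

A female-specific band implies a ZW genotype; its absence implies ZZ.  An
individual is concordant when the call matches its phenotypic sex (F & ZW,
or M & ZZ).  Discordant individuals are annotated as putative sex reversal
or W/Z recombination — the two hypotheses a PCR marker alone cannot
distinguish — never reassigned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .simulate import CohortRecord

__all__ = ["GenotypeCall", "ConcordanceReport", "call_genotype", "concordance_report"]

DISCORDANCE_NOTE = "putative sex reversal or W/Z recombination"


@dataclass(frozen=True)
class GenotypeCall:
    individual_id: str
    band_observed: bool
    genotype_call: str  # 'ZW' iff band observed, else 'ZZ'


@dataclass
class PopulationCounts:
    n_typed: int = 0
    n_concordant: int = 0
    n_discordant: int = 0

    @property
    def concordance_fraction(self) -> float:
        return self.n_concordant / self.n_typed if self.n_typed else float("nan")


@dataclass
class ConcordanceReport:
    """Marker-phenotype concordance, per population and overall."""

    overall: PopulationCounts
    by_population: dict[str, PopulationCounts]
    discordant: pd.DataFrame  # individual_id, population, phenotypic_sex, call, note

    def to_json(self) -> str:
        payload = {
            "overall": vars(self.overall)
            | {"concordance_fraction": self.overall.concordance_fraction},
            "by_population": {
                k: vars(v) | {"concordance_fraction": v.concordance_fraction}
                for k, v in sorted(self.by_population.items())
            },
            "discordant": self.discordant.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_tsv(self, path) -> None:
        rows = [{"population": "overall", **vars(self.overall)}]
        rows += [
            {"population": k, **vars(v)} for k, v in sorted(self.by_population.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def call_genotype(record: CohortRecord) -> GenotypeCall | None:
    """ZW iff the female-specific band is present; None (with a warning) if
    the band observation is missing."""
    if record.band_observed is None:
        warnings.warn(
            f"{record.individual_id}: missing band observation, record skipped",
            stacklevel=2,
        )
        return None
    return GenotypeCall(
        individual_id=record.individual_id,
        band_observed=record.band_observed,
        genotype_call="ZW" if record.band_observed else "ZZ",
    )


def concordance_report(cohort: list[CohortRecord]) -> ConcordanceReport:
    """Summarize marker-phenotype concordance over a genotyped cohort."""
    if not cohort:
        raise ValueError("empty cohort")
    overall = PopulationCounts()
    by_pop: dict[str, PopulationCounts] = {}
    discordant_rows = []
    for record in sorted(cohort, key=lambda r: r.individual_id):
        call = call_genotype(record)
        if call is None:
            continue
        expected = "ZW" if record.phenotypic_sex == "F" else "ZZ"
        concordant = call.genotype_call == expected
        pop = by_pop.setdefault(record.population, PopulationCounts())
        for counts in (overall, pop):
            counts.n_typed += 1
            if concordant:
                counts.n_concordant += 1
            else:
                counts.n_discordant += 1
        if not concordant:
            discordant_rows.append(
                {
                    "individual_id": record.individual_id,
                    "population": record.population,
                    "phenotypic_sex": record.phenotypic_sex,
                    "genotype_call": call.genotype_call,
                    "note": DISCORDANCE_NOTE,
                }
            )
    discordant = pd.DataFrame(
        discordant_rows,
        columns=["individual_id", "population", "phenotypic_sex", "genotype_call", "note"],
    )
    return ConcordanceReport(overall=overall, by_population=by_pop, discordant=discordant)
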