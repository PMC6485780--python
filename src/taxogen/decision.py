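"""Threshold-based taxonomic demarcation.

The rules are the standard taxonogenomic ones: a 16S rRNA identity above
98.65% is compatible with conspecificity (pending genomic confirmation),
between 95% and 98.65% suggests a new species within the genus, and at
or below 95% a possibly new genus. At the genome scale, dDDH below 70%
and AAI below 95% (the lower edge of the conventional 95-96% band)
jointly support a distinct species. Boundary equality always resolves to
the conservative, non-novel side. AGIOS is reported descriptively and
carries no threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .metrics import ComparisonResult

SAME_SPECIES = "same_species"
NEW_SPECIES = "new_species_same_genus"
NEW_GENUS = "possible_new_genus"
INCONCLUSIVE = "inconclusive"

# ordering used by the monotonicity contract: larger = more novel
NOVELTY_RANK = {SAME_SPECIES: 0, INCONCLUSIVE: 1, NEW_SPECIES: 2, NEW_GENUS: 3}


@dataclass(frozen=True)
class Thresholds:
    s16_species: float = 98.65
    s16_genus: float = 95.0
    ddh_species: float = 70.0
    aai_species: float = 95.0

    def __post_init__(self) -> None:
        if not (0 < self.s16_genus < self.s16_species <= 100):
            raise ValueError("16S thresholds must satisfy 0 < genus < species <= 100")
        if not (0 < self.ddh_species <= 100 and 0 < self.aai_species <= 100):
            raise ValueError("genomic thresholds must lie in (0, 100]")


@dataclass
class EvidenceRow:
    metric: str
    value: float
    threshold: float
    passed: bool


@dataclass
class TaxonomicCall:
    verdict: str
    evidence: list[EvidenceRow]
    narrative: str
    subject: str | None = None

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "subject": self.subject,
            "narrative": self.narrative,
            "evidence": [
                {"metric": e.metric, "value": e.value,
                 "threshold": e.threshold, "passed": e.passed}
                for e in self.evidence
            ],
        }


def classify_16s(identity: float, t: Thresholds | None = None,
                 subject: str | None = None) -> TaxonomicCall:
    """Verdict from a 16S rRNA identity percentage alone.

    >= species threshold: conspecificity hypothesis (needs genomic
    confirmation); strictly between the genus and species thresholds: new
    species within the genus; <= genus threshold: possibly a new genus.
    """
    t = t or Thresholds()
    if not (0 <= identity <= 100):
        raise ValueError(f"identity {identity} outside [0, 100]")
    evidence = [
        EvidenceRow("16S_identity_vs_species_threshold", identity,
                    t.s16_species, identity < t.s16_species),
        EvidenceRow("16S_identity_vs_genus_threshold", identity,
                    t.s16_genus, identity > t.s16_genus),
    ]
    if identity >= t.s16_species:
        verdict = SAME_SPECIES
        narrative = (f"16S identity {identity:.2f}% >= {t.s16_species}%: "
                     "consistent with an existing species; requires genomic "
                     "confirmation")
    elif identity > t.s16_genus:
        verdict = NEW_SPECIES
        narrative = (f"16S identity {identity:.2f}% lies between "
                     f"{t.s16_genus}% and {t.s16_species}%: candidate new "
                     "species within the genus")
    else:
        verdict = NEW_GENUS
        narrative = (f"16S identity {identity:.2f}% <= {t.s16_genus}%: "
                     "possibly a new genus")
    return TaxonomicCall(verdict, evidence, narrative, subject)


def classify_genomic(cr: ComparisonResult,
                     t: Thresholds | None = None) -> TaxonomicCall:
    """Verdict from a genome pair's dDDH and AAI.

    Both below their species thresholds: distinct species. Both at or
    above: same species. Disagreement between the two signals is left
    inconclusive with both facts in evidence; it is never auto-resolved.
    """
    t = t or Thresholds()
    below_ddh = cr.ddh < t.ddh_species
    below_aai = cr.aai < t.aai_species
    evidence = [
        EvidenceRow("dDDH", cr.ddh, t.ddh_species, below_ddh),
        EvidenceRow("AAI", cr.aai, t.aai_species, below_aai),
        EvidenceRow("AGIOS", cr.agios, float("nan"), True),
    ]
    if below_ddh and below_aai:
        verdict = NEW_SPECIES
        narrative = (f"dDDH {cr.ddh:.2f}% < {t.ddh_species}% and AAI "
                     f"{cr.aai:.2f}% < {t.aai_species}%: distinct species "
                     f"from {cr.strain_b}")
    elif not below_ddh and not below_aai:
        verdict = SAME_SPECIES
        narrative = (f"dDDH {cr.ddh:.2f}% and AAI {cr.aai:.2f}% both at or "
                     f"above the species thresholds: conspecific with "
                     f"{cr.strain_b}")
    else:
        verdict = INCONCLUSIVE
        narrative = (f"conflicting signals vs {cr.strain_b}: dDDH "
                     f"{cr.ddh:.2f}% ({'below' if below_ddh else 'at/above'} "
                     f"{t.ddh_species}%) but AAI {cr.aai:.2f}% "
                     f"({'below' if below_aai else 'at/above'} "
                     f"{t.aai_species}%)")
    return TaxonomicCall(verdict, evidence, narrative, cr.strain_b)


def species_report(
    strain: str,
    s16: TaxonomicCall,
    genomic: list[TaxonomicCall],
    newick: str | None = None,
) -> dict:
    """Combine the 16S call and all genomic calls into one report.

    The overall verdict is the most specific call supported by every
    line of evidence: with no genomic comparisons the (provisional) 16S
    call stands; a unanimous genomic verdict stands (a high 16S identity
    is only a hypothesis, which the genomic indices adjudicate); mixed or
    inconclusive genomic verdicts yield "inconclusive" with an
    explanation. Output is deterministic for identical inputs.
    """
    notes: list[str] = []
    if not genomic:
        overall = s16.verdict
        notes.append("no genomic comparisons: verdict provisional, "
                     "based on 16S identity alone")
        provisional = True
    else:
        provisional = False
        verdicts = {g.verdict for g in genomic}
        if verdicts == {NEW_SPECIES}:
            overall = NEW_SPECIES
            if s16.verdict == NEW_GENUS:
                notes.append("16S suggested genus-level novelty; genomic "
                             "indices support species-level distinction only")
        elif verdicts == {SAME_SPECIES}:
            if s16.verdict == SAME_SPECIES:
                overall = SAME_SPECIES
            else:
                overall = INCONCLUSIVE
                notes.append("16S and genomic evidence disagree")
        else:
            overall = INCONCLUSIVE
            notes.append("genomic comparisons disagree or are individually "
                         "inconclusive")

    closest = None
    if genomic:
        def aai_of(call: TaxonomicCall) -> float:
            for row in call.evidence:
                if row.metric == "AAI":
                    return row.value
            return float("-inf")
        closest = max(genomic, key=aai_of).subject

    report = {
        "strain": strain,
        "overall_verdict": overall,
        "provisional": provisional,
        "closest_relative": closest,
        "notes": notes,
        "16s_call": s16.to_dict(),
        "genomic_calls": [g.to_dict() for g in genomic],
    }
    if newick is not None:
        report["tree_newick"] = newick
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def report_to_text(report: dict) -> str:
    lines = [
        f"Strain: {report['strain']}",
        f"Overall verdict: {report['overall_verdict']}"
        + (" (provisional)" if report["provisional"] else ""),
    ]
    if report.get("closest_relative"):
        lines.append(f"Closest relative: {report['closest_relative']}")
    lines.append(f"16S: {report['16s_call']['narrative']}")
    for call in report["genomic_calls"]:
        lines.append(f"Genomic vs {call['subject']}: {call['narrative']}")
    for note in report["notes"]:
        lines.append(f"Note: {note}")
    return "\n".join(lines) + "\n"
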