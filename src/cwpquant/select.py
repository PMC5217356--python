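"""Cell-wall-protein selection and functional classification.

A protein counts as a cell-wall protein (CWP) when the secretion
predictors agree it enters the secretory pathway — every signal-peptide
predictor calls "secreted", no organelle-targeting predictor calls
mitochondrial or plastid, and no transmembrane segment remains outside the
signal peptide — and its C-terminus lacks an endoplasmic-reticulum
retention signal (KDEL/HDEL). Selected CWPs are then distributed into nine
functional classes from their predicted functional domains via an ordered,
editable rule table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "ProteinRecord",
    "ClassRuleTable",
    "DEFAULT_CLASS_RULES",
    "FUNCTIONAL_CLASSES",
    "is_secreted_consensus",
    "has_er_retention",
    "select_cwps",
    "classify_functional",
]

SIGNAL_PEPTIDE_PREDICTORS = ("signalp", "phobius")
TARGETING_PREDICTORS = ("targetp", "predotar")

FUNCTIONAL_CLASSES = (
    "PAC",
    "protease",
    "oxido-reductase",
    "lipid metabolism",
    "signaling",
    "interacting with other proteins",
    "structural",
    "miscellaneous",
    "unknown",
)


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    cterm_tail: str
    predictor_calls: dict
    tm_count: int
    domain_labels: frozenset

    @staticmethod
    def from_annotation_row(row) -> "ProteinRecord":
        calls = {tool: (str(getattr(row, tool)).strip() or None)
                 for tool in SIGNAL_PEPTIDE_PREDICTORS + TARGETING_PREDICTORS}
        labels = frozenset(
            x.strip() for x in str(row.domain_labels).split(";") if x.strip())
        return ProteinRecord(
            accession=row.accession,
            cterm_tail=str(row.cterm_tail),
            predictor_calls=calls,
            tm_count=int(row.tmhmm_tm_count),
            domain_labels=labels,
        )


@dataclass
class ClassRuleTable:
    """Ordered domain-label -> functional-class rules; first match wins.

    A rule pattern matches a domain label when they are equal
    (case-insensitive) or when the label is the pattern followed by a
    family number (so the ``GH`` rule covers GH1, GH17, GH28, ...).
    """

    rules: list[tuple[str, str]] = field(default_factory=list)

    def lookup(self, labels: frozenset) -> str | None:
        lowered = {l.lower() for l in labels}
        for pattern, fclass in self.rules:
            pat = pattern.lower()
            for lab in lowered:
                if lab == pat or re.fullmatch(re.escape(pat) + r"\s*\d+", lab):
                    return fclass
        return None

    @staticmethod
    def from_table(df: pd.DataFrame) -> "ClassRuleTable":
        return ClassRuleTable(list(zip(df["domain_label"], df["class"])))

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.rules, columns=["domain_label", "class"])


#: default rules covering the families recurrent in grain cell-wall
#: proteomes: glycoside hydrolases, expansins, carbohydrate esterases,
#: polysaccharide lyases and PNGases are PACs; class III peroxidases are
#: oxido-reductases; lipid transfer proteins fall under lipid metabolism.
DEFAULT_CLASS_RULES = ClassRuleTable([
    ("GH", "PAC"),
    ("glycoside hydrolase", "PAC"),
    ("expansin", "PAC"),
    ("CE", "PAC"),
    ("carbohydrate esterase", "PAC"),
    ("PL", "PAC"),
    ("polysaccharide lyase", "PAC"),
    ("PNGase A", "PAC"),
    ("PNGase", "PAC"),
    ("subtilase", "protease"),
    ("aspartic protease", "protease"),
    ("cysteine protease", "protease"),
    ("serine carboxypeptidase", "protease"),
    ("peroxidase", "oxido-reductase"),
    ("class III peroxidase", "oxido-reductase"),
    ("multicopper oxidase", "oxido-reductase"),
    ("berberine-bridge oxidoreductase", "oxido-reductase"),
    ("LTP", "lipid metabolism"),
    ("lipid transfer protein", "lipid metabolism"),
    ("GDSL lipase", "lipid metabolism"),
    ("receptor-like kinase", "signaling"),
    ("LRR receptor kinase", "signaling"),
    ("lectin", "interacting with other proteins"),
    ("protease inhibitor", "interacting with other proteins"),
    ("extensin", "structural"),
    ("proline-rich protein", "structural"),
    ("germin", "miscellaneous"),
    ("thaumatin", "miscellaneous"),
    ("purple acid phosphatase", "miscellaneous"),
])


def is_secreted_consensus(record: ProteinRecord) -> bool | None:
    """Consensus secretion call over the available predictors.

    Returns True only when every signal-peptide predictor says "secreted",
    no targeting predictor says mitochondrial or plastid, and the
    transmembrane-segment count (outside the signal peptide) is zero.
    Returns None — "unknown" — when any predictor call is missing; callers
    must exclude such proteins explicitly rather than guess.
    """
    calls = record.predictor_calls
    for tool in SIGNAL_PEPTIDE_PREDICTORS + TARGETING_PREDICTORS:
        if calls.get(tool) is None:
            return None
    if record.tm_count < 0:
        return None
    for tool in SIGNAL_PEPTIDE_PREDICTORS:
        if calls[tool] != "secreted":
            return False
    for tool in TARGETING_PREDICTORS:
        if calls[tool] in ("mitochondrial", "plastid"):
            return False
    return record.tm_count == 0


def has_er_retention(cterm_tail: str) -> bool:
    """True iff the final four residues are exactly KDEL or HDEL."""
    if len(cterm_tail) < 4:
        raise ValueError("C-terminal tail must be at least 4 residues")
    return cterm_tail[-4:] in ("KDEL", "HDEL")


def select_cwps(
    records: list[ProteinRecord],
    consensus=is_secreted_consensus,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Select CWPs: consensus-secreted and not ER-retained.

    Returns the selected records plus an exclusion log (accession,
    failed_rule) covering every rejected protein. Selection is a pure
    per-record predicate, hence idempotent and order-independent.
    """
    selected: list[ProteinRecord] = []
    exclusions: list[tuple[str, str]] = []
    for rec in records:
        verdict = consensus(rec)
        if verdict is None:
            exclusions.append((rec.accession, "missing_predictor_call"))
        elif not verdict:
            exclusions.append((rec.accession, "not_consensus_secreted"))
        elif has_er_retention(rec.cterm_tail):
            exclusions.append((rec.accession, "er_retention_signal"))
        else:
            selected.append(rec)
    log = pd.DataFrame(exclusions, columns=["accession", "failed_rule"])
    return selected, log


def classify_functional(
    record: ProteinRecord,
    rules: ClassRuleTable = DEFAULT_CLASS_RULES,
) -> str:
    """Assign one of the nine functional classes from domain labels.

    The first matching rule wins; a protein with no matching (or no)
    domain label is of unknown function.
    """
    return rules.lookup(record.domain_labels) or "unknown"
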