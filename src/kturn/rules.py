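"""Sequence-rule engine for ion-induced k-turn folding and N-class.

Two sequence elements are the key determinants of whether a k-turn
folds into its kinked conformation on addition of metal ions alone:

* the 3b:3n pair following the tandem G:A core — Watson-Crick pairs
  prevent ion-induced folding, while 3b = C or 3n = G confers it;
* the -1b:-1n pair preceding the bulge — C:G confers folding, its
  inversion G:C prevents it, and C:A also prevents it.

Binding of an L7Ae-family protein folds every k-turn regardless of
these sequences, so the protein-induced verdict is a universal
constant.  The tables are table-driven (YAML) so new experimental rows
extend the engine without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

from .annotate import RNA_ALPHABET, WC_PAIRS, KTurnAnnotation

__all__ = [
    "RuleOutcome",
    "FoldingVerdict",
    "RuleConfig",
    "classify_3b3n",
    "classify_m1bm1n",
    "predict_ion_folding",
    "predict_n_class",
]

CONFERS = "confers"
PREVENTS = "prevents"
UNDETERMINED = "undetermined"
_VERDICTS = {CONFERS, PREVENTS, UNDETERMINED}


@dataclass(frozen=True)
class RuleOutcome:
    verdict: str  # confers | prevents | undetermined
    rule_id: str
    basis: str

    def __post_init__(self) -> None:
        if self.verdict not in _VERDICTS:
            raise ValueError(f"invalid verdict {self.verdict!r}")
        if not self.basis:
            raise ValueError("basis must be non-empty")


@dataclass(frozen=True)
class FoldingVerdict:
    """Combined prediction for one k-turn core.

    ``protein_induced`` is constant "folds": every k-turn analyzed to
    date folds on L7Ae binding irrespective of the rule outcomes.
    """

    ion_induced: str  # folds | does_not_fold | undetermined
    n_class_prediction: str  # N1 | N3 | unknown
    trace: tuple[RuleOutcome, ...]
    protein_induced: str = "folds"
    note: str = ""


@dataclass
class RuleConfig:
    """Versioned rule tables; defaults ship with the package."""

    confers_if_b: frozenset[str] = frozenset({"C"})
    confers_if_n: frozenset[str] = frozenset({"G"})
    wc_prevents: bool = True
    confers_over_prevents: bool = True
    m1_table: Mapping[tuple[str, str], str] = field(
        default_factory=lambda: {("C", "G"): CONFERS, ("G", "C"): PREVENTS,
                                 ("C", "A"): PREVENTS})
    n_class_table: Mapping[tuple[str, str], str] = field(
        default_factory=lambda: {("A", "U"): "N3"})
    version: int = 1

    @classmethod
    def from_yaml(cls, source=None) -> "RuleConfig":
        """Load rule tables from a YAML file (None -> packaged default)."""
        if source is None:
            text = (resources.files("kturn") / "data" / "rules.yaml").read_text()
        else:
            with open(source) as fh:
                text = fh.read()
        doc = yaml.safe_load(text)
        t3 = doc.get("three_b_three_n", {})
        m1 = {_parse_pair(k): v for k, v in doc.get("minus1b_minus1n", {}).items()}
        nc = {_parse_pair(k): str(v) for k, v in doc.get("n_class", {}).items()}
        return cls(
            confers_if_b=frozenset(t3.get("confers_if_b", ["C"])),
            confers_if_n=frozenset(t3.get("confers_if_n", ["G"])),
            wc_prevents=bool(t3.get("watson_crick_prevents", True)),
            confers_over_prevents=(
                t3.get("precedence", "confers_over_prevents")
                == "confers_over_prevents"),
            m1_table=m1 if m1 else dict(cls().m1_table),
            n_class_table=nc,
            version=int(doc.get("version", 1)),
        )


def _parse_pair(key: str) -> tuple[str, str]:
    b, n = str(key).split(":")
    return (b.strip().upper(), n.strip().upper())


_DEFAULT = RuleConfig()


def _check_bases(pair: tuple[str, str]) -> None:
    for base in pair:
        if base not in RNA_ALPHABET:
            raise ValueError(f"invalid RNA base {base!r}")


def classify_3b3n(pair: tuple[str, str],
                  config: RuleConfig = _DEFAULT) -> RuleOutcome:
    """Classify the 3b:3n pair for ion-induced folding.

    3b = C or 3n = G confers folding; Watson-Crick pairs prevent it;
    with both applicable (C:G) the conferring clause takes precedence by
    default.  Everything else is undetermined.
    """
    _check_bases(pair)
    b, n = pair
    confers = b in config.confers_if_b or n in config.confers_if_n
    prevents = config.wc_prevents and (b, n) in WC_PAIRS
    if confers and prevents:
        verdict = CONFERS if config.confers_over_prevents else PREVENTS
        basis = "3b=C / 3n=G conferring clause vs Watson-Crick prevention; " \
                "configured precedence applied"
    elif confers:
        verdict, basis = CONFERS, "3b = C or 3n = G confers ion-induced folding"
    elif prevents:
        verdict, basis = PREVENTS, "Watson-Crick 3b:3n pair prevents ion-induced folding"
    else:
        verdict, basis = UNDETERMINED, "3b:3n pair not covered by the shipped table"
    return RuleOutcome(verdict, rule_id=f"3b3n:{b}:{n}", basis=basis)


def classify_m1bm1n(pair: tuple[str, str],
                    config: RuleConfig = _DEFAULT) -> RuleOutcome:
    """Classify the -1b:-1n pair: C:G confers, G:C and C:A prevent,
    all other pairs are undetermined (no systematic study exists)."""
    _check_bases(pair)
    verdict = config.m1_table.get(tuple(pair), UNDETERMINED)
    basis = {
        CONFERS: "-1b:-1n = C:G confers folding in metal ions",
        PREVENTS: f"-1b:-1n = {pair[0]}:{pair[1]} prevents ion-induced folding",
        UNDETERMINED: "-1b:-1n pair has no measured folding behaviour",
    }[verdict]
    return RuleOutcome(verdict, rule_id=f"m1bm1n:{pair[0]}:{pair[1]}", basis=basis)


def predict_n_class(annotation_or_pair,
                    config: RuleConfig = _DEFAULT) -> str:
    """Predicted core conformation (N1/N3/unknown) from the 3b:3n pair.

    Table-driven; the shipped table carries A:U -> N3 (confirmed
    crystallographically for this motif) and is user-extensible.
    """
    pair = _pair_of(annotation_or_pair, 3)
    return config.n_class_table.get(tuple(pair), "unknown")


def _pair_of(annotation_or_pair, number: int) -> tuple[str, str]:
    if isinstance(annotation_or_pair, KTurnAnnotation):
        return annotation_or_pair.pair(number)
    pair = tuple(annotation_or_pair)
    if len(pair) != 2:
        raise ValueError("expected a (b, n) base pair or a KTurnAnnotation")
    return pair  # type: ignore[return-value]


def predict_ion_folding(annotation: KTurnAnnotation | dict,
                        config: RuleConfig = _DEFAULT) -> FoldingVerdict:
    """Combine the -1b:-1n and 3b:3n rules into a folding verdict.

    Any "prevents" dominates -> does_not_fold; otherwise any "confers"
    -> folds (with a confidence note when the other rule is
    undetermined); otherwise undetermined.  The trace always records
    both rule outcomes, and protein_induced is always "folds".
    """
    if isinstance(annotation, dict):
        m1, p3 = annotation["-1"], annotation["3"]
    else:
        try:
            m1, p3 = annotation.pair(-1), annotation.pair(3)
        except Exception as exc:
            raise ValueError(f"incomplete annotation: {exc}") from exc
    r1 = classify_m1bm1n(m1, config)
    r3 = classify_3b3n(p3, config)
    trace = (r1, r3)
    verdicts = {r.verdict for r in trace}
    note = ""
    if PREVENTS in verdicts:
        ion = "does_not_fold"
        if CONFERS in verdicts:
            note = "conflicting rules: one element confers, the other prevents"
    elif CONFERS in verdicts:
        ion = "folds"
        if UNDETERMINED in verdicts:
            note = ("one element confers, the other is unmeasured; "
                    "verdict carries reduced confidence")
    else:
        ion = "undetermined"
    return FoldingVerdict(
        ion_induced=ion,
        n_class_prediction=predict_n_class(p3, config),
        trace=trace,
        note=note,
    )
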