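"""Controlled substrate vocabulary and conservative descriptor harmonisation.

Occurrence archives record the microhabitat of each sporocarp observation as
free text ("bark of living oak trunk", "moss on rotten log", ...).  Analyses
operate on a consolidated ten-class substrate scheme; assignment to a class is
made only when the verbatim descriptor maps unambiguously to exactly one class.
Ambiguous or mixed descriptors are deliberately left unassigned — a missing
substrate code is a value, not an error.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

import yaml

#: The ten consolidated substrate class codes.
SUBSTRATE_CODES = ("COR", "LIG", "RAM", "FOL", "BRY", "HER", "TER", "SAX", "XYL", "MSC")

#: Human-readable category names.
SUBSTRATE_NAMES = {
    "COR": "Corticolous",
    "LIG": "Lignicolous",
    "RAM": "Ramicolous",
    "FOL": "Foliicolous",
    "BRY": "Bryophilous",
    "HER": "Herbaceous",
    "TER": "Terricolous",
    "SAX": "Saxicolous",
    "XYL": "Xylophilous",
    "MSC": "Miscellaneous",
}

# Default English keyword rule set.  Each pattern is a case-folded regular
# expression matched against the normalised descriptor.  The rule list is a
# faithful reading of the class definitions (bark / structural dead wood in
# decay / fine twigs / leaves and needles / moss mats / herbaceous stems /
# soil and surface litter / rock / processed wood / explicitly indeterminate);
# it is config-extensible and replaceable via YAML for other languages.
DEFAULT_RULES: dict[str, tuple[str, ...]] = {
    "COR": (
        r"\bbark\b",
        r"\bperiderm\b",
        r"\bcorticolous\b",
        r"\bcortex\b",
    ),
    "LIG": (
        r"\blogs?\b",
        r"\bstumps?\b",
        r"\bsnags?\b",
        r"\bdead wood\b",
        r"\bdeadwood\b",
        r"\b(?:decay(?:ed|ing)?|rott(?:en|ing)|decompos(?:ed|ing)) (?:wood|trunk|branch)\b",
        r"\bstanding (?:dead )?trunks?\b",
        r"\bcoarse woody debris\b",
        r"\blignicolous\b",
        r"\bxylem\b",
    ),
    "RAM": (
        r"\btwigs?\b",
        r"\bfine branch(?:es)?\b",
        r"\bbranchlets?\b",
        r"\bramicolous\b",
    ),
    "FOL": (
        r"\bleaf\b",
        r"\bleaves\b",
        r"\bneedles?\b",
        r"\bfrond\b",
        r"\bfoliicolous\b",
    ),
    "BRY": (
        r"\bmoss(?:es|y)?\b",
        r"\bbryophytes?\b",
        r"\bliverworts?\b",
        r"\bgametophytes?\b",
        r"\bbryophilous\b",
    ),
    "HER": (
        r"\bherbaceous\b",
        r"\bgrass(?:es)?\b",
        r"\bforbs?\b",
        r"\bferns?\b",
        r"\bdwarf shrubs?\b",
        r"\bherb stems?\b",
    ),
    "TER": (
        r"\bsoil\b",
        r"\bhumus\b",
        r"\bground litter\b",
        r"\bsurface litter\b",
        r"\bforest floor\b",
        r"\bterricolous\b",
    ),
    "SAX": (
        r"\brocks?\b",
        r"\bstones?\b",
        r"\bboulders?\b",
        r"\bsaxicolous\b",
        r"\bmineral substrat",
    ),
    "XYL": (
        r"\bsawn\b",
        r"\btimber\b",
        r"\bboards?\b",
        r"\bplanks?\b",
        r"\bwooden construction\b",
        r"\bprocessed wood\b",
        r"\bfence post\b",
        r"\bxylophilous\b",
    ),
    "MSC": (
        r"\bunspecified\b",
        r"\bindeterminate\b",
        r"\bunknown substrate\b",
        r"\bunidentified substrate\b",
        r"\bdecaying organic matter\b",
    ),
}

#: One canonical descriptor per code; each matches exactly one rule, so
#: generated archives round-trip through harmonisation without failures.
CANONICAL_DESCRIPTORS = {
    "COR": "bark of living tree",
    "LIG": "decaying log",
    "RAM": "fallen twigs",
    "FOL": "dead leaves",
    "BRY": "living moss mat",
    "HER": "senescent grass stems",
    "TER": "upper soil horizon",
    "SAX": "exposed rock",
    "XYL": "sawn wooden fence post",
    "MSC": "unspecified decaying organic matter",
}


def _normalise(text: str) -> str:
    """Case-fold and strip diacritics so matching is accent/case-insensitive."""
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    return re.sub(r"\s+", " ", text.casefold()).strip()


@dataclass
class SubstrateVocabulary:
    """Ten-class substrate vocabulary with deterministic descriptor rules."""

    rules: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {c: tuple(p) for c, p in DEFAULT_RULES.items()}
    )

    def __post_init__(self) -> None:
        if set(self.rules) != set(SUBSTRATE_CODES):
            raise ValueError(
                f"vocabulary must define exactly the codes {SUBSTRATE_CODES}"
            )
        self._compiled = {
            code: [re.compile(p) for p in pats] for code, pats in self.rules.items()
        }

    @property
    def codes(self) -> tuple[str, ...]:
        return SUBSTRATE_CODES

    def matching_codes(self, descriptor: str) -> list[str]:
        """All codes with at least one matching rule, in canonical code order."""
        text = _normalise(descriptor)
        return [
            code
            for code in SUBSTRATE_CODES
            if any(rx.search(text) for rx in self._compiled[code])
        ]

    def harmonise(self, descriptor) -> str | None:
        """Map a verbatim descriptor to a single substrate code, or None.

        Exactly one matching class is required; zero matches or a mixed
        descriptor matching several classes yields None (conservative
        non-assignment).  MSC is returned only when the descriptor explicitly
        signals an indeterminate substrate (its rules match nothing else).
        """
        if descriptor is None or (isinstance(descriptor, float)) or descriptor == "":
            return None
        matches = self.matching_codes(str(descriptor))
        if len(matches) == 1:
            return matches[0]
        return None

    # -- YAML round-trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            code: {
                "name": SUBSTRATE_NAMES[code],
                "patterns": list(self.rules[code]),
            }
            for code in SUBSTRATE_CODES
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SubstrateVocabulary":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        rules = {code: tuple(entry["patterns"]) for code, entry in payload.items()}
        return cls(rules=rules)


def harmonise_substrate(descriptor, vocab: SubstrateVocabulary | None = None):
    """Functional wrapper: map one verbatim descriptor to a code or None."""
    vocab = vocab or SubstrateVocabulary()
    return vocab.harmonise(descriptor)
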