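"""Gene panels and label vocabularies.

The assay panels are fixed, ordered lists of gene symbols. Order matters:
discriminant coefficients, serialized models and report tables all follow
panel order.
"""

from __future__ import annotations

from dataclasses import dataclass, field


REFERENCE_GENE = "ACTB"

# label vocabulary for the two classification tasks
HIGHER_RISK = "higher_risk"
LOWER_RISK = "lower_risk"
CANCER = "cancer"
BENIGN = "benign"
UNKNOWN = "unknown"

VALID_LABELS = frozenset({HIGHER_RISK, LOWER_RISK, CANCER, BENIGN, UNKNOWN})


@dataclass(frozen=True)
class GenePanel:
    """An ordered, duplicate-free collection of gene symbols."""

    name: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.name!r} has duplicate gene symbols")
        if REFERENCE_GENE in self.genes:
            raise ValueError(
                f"reference gene {REFERENCE_GENE} cannot be a panel member"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def index(self, gene: str) -> int:
        return self.genes.index(gene)


#: The 14-gene urinary panel used for risk stratification and diagnosis.
PANEL14 = GenePanel(
    "PANEL14",
    (
        "PMP22", "GOLM1", "LMTK2", "EZH2", "GSTP1", "PCA3", "VEGFA",
        "CST3", "PTEN", "PIP5K1A", "CDK1", "TMPRSS2", "ANXA3", "CCND1",
    ),
)

#: The earlier 8-gene tissue panel (tissue cohorts only).
PANEL8 = GenePanel(
    "PANEL8",
    ("PMP22", "GOLM1", "LMTK2", "EZH2", "GSTP1", "PCA3", "HPN", "FN1"),
)

#: The 6-gene subset of the 8-gene panel.
PANEL6 = GenePanel("PANEL6", PANEL8.genes[:6])

PANELS = {"14": PANEL14, "8": PANEL8, "6": PANEL6,
          "PANEL14": PANEL14, "PANEL8": PANEL8, "PANEL6": PANEL6}


def get_panel(key) -> GenePanel:
    """Resolve a panel preset from a name/size key, or pass through a GenePanel."""
    if isinstance(key, GenePanel):
        return key
    try:
        return PANELS[str(key)]
    except KeyError:
        raise KeyError(
            f"unknown panel {key!r}; choose one of 14, 8, 6"
        ) from None
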