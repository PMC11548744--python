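"""Study design description for the multi-organ qPCR time course.

The default design mirrors a longitudinal hypertension study in the
spontaneously hypertensive rat (SHR) and its normotensive Wistar-Kyoto
(WKY) control: five visceral organs sampled cross-sectionally at five
ages spanning pre-hypertension (8 weeks) through chronic hypertension
(24 weeks), three animals per (strain, organ, age) cell, and a 96-gene
panel covering renin-angiotensin (RAS), sympathetic, inflammatory,
metabolic and fibrotic pathways plus housekeeping candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

PATHWAYS = ("inflammation", "RAS", "sympathetic", "metabolism", "fibrosis", "other")

#: visceral organs of the female cohort
PERIPHERAL_ORGANS = ("adrenal", "kidney", "liver", "lung", "spleen")

#: brainstem autonomic regions available as additional network nodes
BRAINSTEM_REGIONS = ("RVLM", "CVLM", "NTS")

_GENE_PANEL: dict[str, tuple[str, ...]] = {
    "RAS": (
        "Ren", "Agt", "Ace", "Ace2", "Agtr1a", "Agtr2", "Agtrap", "Renbp",
        "Mas1", "Ctsd", "Cma1", "Apln", "Aplnr",
    ),
    "sympathetic": (
        "Th", "Dbh", "Pnmt", "Ddc", "Nts", "Ntsr1", "Hcrtr1", "Adra1a",
        "Adra1b", "Adra2a", "Adrb1", "Adrb2", "Adrb3", "Chga", "Npy",
        "Slc6a2", "Gja1",
    ),
    "inflammation": (
        "Il1b", "Il6", "Il10", "Il18", "Tnf", "Ccl2", "Ccl5", "Cxcl1",
        "Icam1", "Vcam1", "Nfkb1", "Tlr4", "Hmgb1", "Bcl6", "Ptgs2",
        "Nos2", "Ifng", "Ccr2", "Cd68", "Il1rn",
    ),
    "metabolism": (
        "Ephx2", "Cyp11b1", "Cyp11b2", "Cyp19a1", "Hsd11b1", "Hsd11b2",
        "Nr3c1", "Nr3c2", "Esr1", "Lep", "Lepr", "Insr", "Slc2a1",
        "Ppara", "Pparg", "Sirt1", "Ucp2", "Sod2", "Cat", "Gpx1",
        "Nox4", "Arg2", "Hif1a",
    ),
    "fibrosis": (
        "Tgfb1", "Col1a1", "Col3a1", "Col4a1", "Fn1", "Mmp2", "Mmp9",
        "Timp1", "Acta2", "Ctgf", "Serpine1", "Eln", "Vim",
    ),
    "other": (
        "Actb", "Gapdh", "B2m", "Hprt1", "Ppia", "Rpl13a", "Ywhaz",
        "Ubc", "Pgk1", "Tbp",
    ),
}


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the expression time course.

    Parameters
    ----------
    organs
        Organ / brain-region labels; each sample comes from one organ.
    strains
        Rat strains compared (e.g. ``("SHR", "WKY")``).
    ages_weeks
        Sampling ages in weeks, strictly increasing.
    replicates_per_cell
        Animals per (strain, organ, age) cell; the study uses 3.
    genes
        Unique gene labels of the qPCR panel.
    pathway
        Gene -> pathway tag mapping; missing genes default to ``"other"``.
    sex
        Sex label attached to every sample of the cohort.
    """

    organs: tuple[str, ...]
    strains: tuple[str, ...]
    ages_weeks: tuple[float, ...]
    replicates_per_cell: int
    genes: tuple[str, ...]
    pathway: dict[str, str] = field(default_factory=dict)
    sex: str = "F"

    def __post_init__(self) -> None:
        ages = tuple(self.ages_weeks)
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages_weeks must be strictly increasing")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene labels must be unique")
        bad = set(self.pathway.values()) - set(PATHWAYS)
        if bad:
            raise ValueError(f"unknown pathway tags: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        """Biological samples before missingness/duplication."""
        return (len(self.strains) * len(self.organs) * len(self.ages_weeks)
                * self.replicates_per_cell)

    @property
    def n_nodes(self) -> int:
        """Network nodes: every (organ, gene) pair."""
        return len(self.organs) * len(self.genes)

    def node_labels(self) -> list[tuple[str, str]]:
        return [(o, g) for o in self.organs for g in self.genes]

    def pathway_of(self, gene: str) -> str:
        return self.pathway.get(gene, "other")


def default_gene_panel() -> tuple[tuple[str, ...], dict[str, str]]:
    """The 96-gene multi-pathway panel and its pathway tags."""
    genes: list[str] = []
    pathway: dict[str, str] = {}
    for tag, names in _GENE_PANEL.items():
        genes.extend(names)
        pathway.update({g: tag for g in names})
    return tuple(genes), pathway


def female_design(replicates_per_cell: int = 3,
                  include_brainstem: bool = False) -> StudyDesign:
    """Design of the female cohort: 2 strains x 5 ages x 5 organs x 3 animals.

    ``include_brainstem=True`` appends the three autonomic brainstem
    regions used as extra network nodes in the modeling stage.
    """
    organs = PERIPHERAL_ORGANS + (BRAINSTEM_REGIONS if include_brainstem else ())
    genes, pathway = default_gene_panel()
    return StudyDesign(
        organs=organs,
        strains=("SHR", "WKY"),
        ages_weeks=(8.0, 10.0, 12.0, 16.0, 24.0),
        replicates_per_cell=replicates_per_cell,
        genes=genes,
        pathway=pathway,
        sex="F",
    )


def male_design(replicates_per_cell: int = 3, n_genes: int = 17) -> StudyDesign:
    """Reduced male-cohort design: 3 organs, 3 ages, a 17-gene shared panel."""
    genes, pathway = default_gene_panel()
    genes = genes[:n_genes]
    return StudyDesign(
        organs=("adrenal", "kidney", "liver"),
        strains=("SHR", "WKY"),
        ages_weeks=(8.0, 12.0, 16.0),
        replicates_per_cell=replicates_per_cell,
        genes=genes,
        pathway={g: pathway[g] for g in genes},
        sex="M",
    )


def toy_design(n_organs: int = 3, n_genes: int = 5,
               ages: Sequence[float] = (8.0, 10.0, 12.0, 16.0, 24.0),
               replicates_per_cell: int = 3,
               strains: Sequence[str] = ("SHR", "WKY")) -> StudyDesign:
    """Small design for tests and recovery studies (default 15 nodes)."""
    all_genes, pathway = default_gene_panel()
    genes = all_genes[:n_genes]
    return StudyDesign(
        organs=PERIPHERAL_ORGANS[:n_organs],
        strains=tuple(strains),
        ages_weeks=tuple(ages),
        replicates_per_cell=replicates_per_cell,
        genes=genes,
        pathway={g: pathway[g] for g in genes},
    )
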