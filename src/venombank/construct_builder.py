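"""Fusion-construct assembly and annotation.

Peptides are expressed in the E. coli periplasm as DsbC fusions: an
N-terminal DsbC carrier (with export signal), an internal hexa-histidine tag
for IMAC capture and a TEV recognition site (ENLYFQ/X).  TEV cleaves after
the Q, releasing the native peptide with no extra N-terminal residue.

The exact carrier sequence is proprietary configuration; when only a carrier
mass is known (default 27,787 Da, chosen so that a 5935-Da peptide is 17.6 %
of the fusion) the module works mass-only.  The mass-only carrier constant is
defined as already accounting for the peptide-bond junction, so the fusion
mass is simply ``carrier_mass + peptide_mass`` -- a documented convention,
not a chemistry statement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .codon_design import CodonTable, back_translate_initial
from .mass_qc import peptide_mass
from .peptide_io import PeptideRecord

TEV_SITE = "ENLYFQ"
DEFAULT_CARRIER_MASS_DA = 27_787.0


@dataclass(frozen=True)
class CarrierSpec:
    """The fusion carrier: a protein sequence, or a bare average mass."""

    name: str = "DsbC-His6"
    sequence: str | None = None
    mass_da: float | None = DEFAULT_CARRIER_MASS_DA
    notes: str = ""

    def __post_init__(self) -> None:
        if self.sequence is None and self.mass_da is None:
            raise ValueError("carrier needs a sequence or a mass")
        if self.mass_da is not None and self.mass_da <= 0:
            raise ValueError("carrier mass must be positive")

    @property
    def average_mass(self) -> float:
        if self.sequence is not None:
            return peptide_mass(self.sequence, "average")
        return float(self.mass_da)


@dataclass(frozen=True)
class ConstructRecord:
    """One annotated fusion construct (sequence-level when available)."""

    peptide_id: str
    fusion_protein: str | None
    dna: str | None
    fusion_mass_avg: float
    peptide_mass_avg: float
    protein_features: tuple[tuple[str, int, int], ...] = ()
    dna_features: tuple[tuple[str, int, int], ...] = ()

    @property
    def mass_fraction(self) -> float:
        return self.peptide_mass_avg / self.fusion_mass_avg

    def cleave(self) -> str:
        """TEV cleavage product: everything after the ENLYFQ site."""
        if self.fusion_protein is None:
            raise ValueError("mass-only construct has no sequence to cleave")
        idx = self.fusion_protein.rindex(TEV_SITE)
        return self.fusion_protein[idx + len(TEV_SITE):]


def carrier_mass_from_sequence(carrier_sequence: str) -> float:
    """Mass-only carrier constant equivalent to a sequence carrier.

    The constant covers everything upstream of the peptide -- carrier body
    plus the TEV site -- with the junction water already accounted for, so
    that ``constant + peptide_mass`` equals the residue-level fusion mass.
    """
    from pyteomics import mass as pmass

    water = pmass.calculate_mass(formula="H2O", average=True)
    return peptide_mass(carrier_sequence + TEV_SITE, "average") - water


def fusion_mass(peptide_mass_da: float, carrier: CarrierSpec) -> float:
    """Average fusion mass for a given peptide mass.

    Sequence carriers are summed at residue level in :func:`build_fusion`;
    for mass-only carriers the constant is defined as TEV-site- and
    junction-inclusive (see :func:`carrier_mass_from_sequence`), so the
    fusion mass is the plain sum ``carrier_mass + peptide_mass`` with no
    further water correction.
    """
    if peptide_mass_da <= 0:
        raise ValueError("peptide mass must be positive")
    return carrier.average_mass + peptide_mass_da


def build_fusion(peptide: PeptideRecord, gene=None,
                 carrier: CarrierSpec | None = None,
                 table: CodonTable | None = None) -> ConstructRecord:
    """Assemble the DsbC(-His6)-TEV-peptide fusion for one peptide.

    With a sequence carrier the full protein (and a back-translated DNA
    record suitable for GenBank annotation) is built; the carrier sequence
    is expected to already contain the internal His6 tag, located for
    annotation as its last ``HHHHHH`` occurrence.  With a mass-only carrier
    a composite-mass construct is returned.
    """
    carrier = carrier or CarrierSpec()
    pep_mass = peptide_mass(peptide.sequence, "average")

    if carrier.sequence is None:
        return ConstructRecord(
            peptide_id=peptide.id,
            fusion_protein=None,
            dna=None,
            fusion_mass_avg=fusion_mass(pep_mass, carrier),
            peptide_mass_avg=pep_mass,
        )

    protein = carrier.sequence + TEV_SITE + peptide.sequence
    lc = len(carrier.sequence)
    prot_feats = [("carrier", 0, lc)]
    his = carrier.sequence.rfind("HHHHHH")
    if his != -1:
        prot_feats.append(("his6", his, his + 6))
    prot_feats.append(("tev_site", lc, lc + len(TEV_SITE)))
    prot_feats.append(("peptide", lc + len(TEV_SITE), len(protein)))

    dna = None
    dna_feats: list[tuple[str, int, int]] = []
    if gene is not None:
        table = table or CodonTable.default()
        carrier_dna = back_translate_initial(carrier.sequence, table)
        dna = carrier_dna + gene.cds
        off = len(carrier_dna)
        dna_feats = [("carrier", 0, off)]
        if his != -1:
            dna_feats.append(("his6", 3 * his, 3 * (his + 6)))
        dna_feats.append(("tev_site", off, off + 18))
        dna_feats.append(("peptide", off + 18, len(dna) - 6))
        dna_feats.append(("stop", len(dna) - 6, len(dna)))

    return ConstructRecord(
        peptide_id=peptide.id,
        fusion_protein=protein,
        dna=dna,
        fusion_mass_avg=peptide_mass(protein, "average"),
        peptide_mass_avg=pep_mass,
        protein_features=tuple(prot_feats),
        dna_features=tuple(dna_feats),
    )


def annotate_genbank(construct: ConstructRecord, path) -> None:
    """Write the construct DNA as an annotated GenBank record."""
    if construct.dna is None:
        raise ValueError("construct has no DNA to annotate")
    record = SeqRecord(
        Seq(construct.dna),
        id=construct.peptide_id[:16],
        name=construct.peptide_id[:16],
        description=f"DsbC fusion construct for {construct.peptide_id}",
        annotations={"molecule_type": "DNA"},
    )
    for label, start, end in construct.dna_features:
        record.features.append(
            SeqFeature(FeatureLocation(start, end), type="misc_feature",
                       qualifiers={"label": [label]})
        )
    SeqIO.write([record], str(path), "genbank")


def read_genbank_features(path) -> tuple[tuple[str, int, int], ...]:
    """Round-trip helper: feature table of an annotated construct file."""
    record = SeqIO.read(str(path), "genbank")
    return tuple(
        (f.qualifiers["label"][0], int(f.location.start), int(f.location.end))
        for f in record.features
    )
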