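"""LWS allele classification from exon 4/5 amplicon sequence.

The two LWS haplotypes segregating in *Pundamilia* ("H", typical of the
red species, and "P", typical of the blue species) differ at three
diagnostic amino-acid positions: 216 (Y/F), 230 (A/T) and 275 (C/I),
located on exons 4 and 5.  Individuals are classified from Sanger
amplicon sequence: all three residues H-type -> HH, all P-type -> PP,
an IUPAC ambiguity code compatible with both alleles at any site
(double peaks in the trace) -> HET; any other pattern is UNRESOLVED.
Unsequenced females can be imputed from the pedigree when the parental
genotypes force a unique offspring genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

DIAGNOSTIC_RESIDUES = (216, 230, 275)

# residue identities defining each allele at the three diagnostic sites
H_RESIDUES = {216: "Y", 230: "A", 275: "C"}
P_RESIDUES = {216: "F", 230: "T", 275: "I"}

GENOTYPES = ("HH", "PP", "HET", "UNRESOLVED")


class TruncatedAmpliconError(ValueError):
    """A diagnostic codon falls outside the supplied sequence."""


class FrameError(ValueError):
    """An unambiguous in-frame stop codon in the translated region."""


@dataclass(frozen=True)
class AmpliconLayout:
    """Coordinate frame of the sequenced LWS fragment.

    0-based half-open spans on the amplicon; ``first_residue`` is the
    protein residue number encoded by the first in-frame codon of the
    spliced exonic sequence, ``frame_offset`` the number of exonic bases
    preceding that codon.  The packaged default is a 498-bp amplicon with
    a 91-bp intron separating exon 4 from exon 5, oriented so that the
    three diagnostic codons fall inside the exons.
    """

    exon4: tuple = (0, 250)
    intron: tuple = (250, 341)
    exon5: tuple = (341, 498)
    first_residue: int = 180
    frame_offset: int = 0

    def exonic_coord(self, residue: int) -> int:
        """Offset of a residue's codon within the spliced exonic sequence."""
        return self.frame_offset + 3 * (residue - self.first_residue)

    def amplicon_coord(self, residue: int) -> int:
        """Amplicon coordinate of a residue's first base."""
        pos = self.exonic_coord(residue)
        e4_len = self.exon4[1] - self.exon4[0]
        if pos < e4_len:
            return self.exon4[0] + pos
        return self.exon5[0] + (pos - e4_len)


DEFAULT_LAYOUT = AmpliconLayout()


@dataclass(frozen=True)
class LwsAmplicon:
    sequence_id: str
    bases: str
    layout: AmpliconLayout = DEFAULT_LAYOUT


@dataclass
class GenotypeCall:
    female_id: str
    genotype: str                      # HH | PP | HET | UNRESOLVED
    evidence: str                      # sequenced | pedigree_imputed
    per_site: dict = field(default_factory=dict)  # residue -> site call
    flags: set = field(default_factory=set)


def _expand_triplet(triplet: str) -> set:
    """All unambiguous codons an IUPAC triplet can stand for."""
    codons = {""}
    for base in triplet.upper():
        try:
            choices = ambiguous_dna_values[base]
        except KeyError:
            raise ValueError(f"invalid nucleotide code {base!r}") from None
        codons = {c + b for c in codons for b in choices}
    return codons


def _site_call(triplet: str, residue: int) -> str:
    """Classify one diagnostic triplet: 'H', 'P', 'HET' or 'NEITHER'."""
    aas = set()
    for codon in _expand_triplet(triplet):
        aas.add(standard_dna_table.forward_table.get(codon, "*"))
    has_h = H_RESIDUES[residue] in aas
    has_p = P_RESIDUES[residue] in aas
    if has_h and has_p:
        return "HET"
    if has_h:
        return "H"
    if has_p:
        return "P"
    return "NEITHER"


def spliced_exonic(amplicon: LwsAmplicon) -> str:
    lay = amplicon.layout
    seq = amplicon.bases.upper()
    return seq[slice(*lay.exon4)] + seq[slice(*lay.exon5)]


def extract_codons(amplicon: LwsAmplicon, orientation: str = "forward") -> dict:
    """Splice out the intron and return the three diagnostic triplets.

    Returns {residue: (triplet, amplicon_start)}.  ``orientation="reverse"``
    reverse-complements the input first (the layout then applies to the
    corrected strand).  Raises TruncatedAmpliconError when a codon falls
    outside the sequence and FrameError on an unambiguous in-frame stop.
    """
    if orientation == "reverse":
        amplicon = LwsAmplicon(amplicon.sequence_id,
                               str(Seq(amplicon.bases).reverse_complement()),
                               amplicon.layout)
    elif orientation != "forward":
        raise ValueError("orientation must be 'forward' or 'reverse'")
    lay = amplicon.layout
    exonic = spliced_exonic(amplicon)
    out = {}
    for residue in DIAGNOSTIC_RESIDUES:
        pos = lay.exonic_coord(residue)
        if pos < 0 or pos + 3 > len(exonic):
            raise TruncatedAmpliconError(
                f"codon {residue} outside amplicon {amplicon.sequence_id}")
        out[residue] = (exonic[pos:pos + 3], lay.amplicon_coord(residue))
    # frame check over the fully determined codons of the translated region
    for i in range(lay.frame_offset, len(exonic) - 2, 3):
        codon = exonic[i:i + 3]
        if set(codon) <= set("ACGT") and codon in standard_dna_table.stop_codons:
            raise FrameError(
                f"in-frame stop at exonic position {i} in {amplicon.sequence_id}")
    return out


def classify_allele(per_site: dict) -> str:
    """Map the three per-site triplet calls onto a genotype class.

    ``per_site``: {residue: triplet} or the output of extract_codons.
    Total over its domain: every input yields exactly one of HH, PP, HET
    or UNRESOLVED (mixed pure H/P patterns without ambiguity stay
    unresolved rather than being forced).
    """
    calls = {}
    for residue in DIAGNOSTIC_RESIDUES:
        if residue not in per_site:
            raise ValueError(f"missing diagnostic residue {residue}")
        trip = per_site[residue]
        if isinstance(trip, tuple):
            trip = trip[0]
        calls[residue] = _site_call(trip, residue)
    values = set(calls.values())
    if "NEITHER" in values:
        return "UNRESOLVED"
    if "HET" in values:
        return "HET"
    if values == {"H"}:
        return "HH"
    if values == {"P"}:
        return "PP"
    return "UNRESOLVED"


def call_amplicon(amplicon: LwsAmplicon, female_id: str | None = None,
                  orientation: str = "forward") -> GenotypeCall:
    per_site = extract_codons(amplicon, orientation=orientation)
    site_calls = {r: _site_call(t, r) for r, (t, _) in per_site.items()}
    return GenotypeCall(female_id or amplicon.sequence_id,
                        classify_allele(per_site), "sequenced", site_calls)


def call_fasta(path, layout: AmpliconLayout = DEFAULT_LAYOUT,
               orientation: str = "forward") -> dict:
    """Genotype every record of a FASTA file of LWS amplicons."""
    calls = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        amp = LwsAmplicon(rec.id, str(rec.seq), layout)
        calls[rec.id] = call_amplicon(amp, orientation=orientation)
    return calls


# ---------------------------------------------------------------------------
# pedigree imputation

_FORCED_OFFSPRING = {
    frozenset(["PP"]): "PP",           # PP x PP
    frozenset(["HH"]): "HH",           # HH x HH
    frozenset(["PP", "HH"]): "HET",    # PP x HH either way
}


def forced_offspring(dam_genotype: str, sire_genotype: str) -> str | None:
    """Offspring genotype when the parental pair admits only one, else None."""
    return _FORCED_OFFSPRING.get(frozenset([dam_genotype, sire_genotype]))


def pedigree_impute(calls: dict, pedigree: pd.DataFrame) -> dict:
    """Fill in unsequenced females from parental genotypes.

    ``pedigree`` columns: female_id, dam_genotype, sire_genotype.  A
    female is imputed only when the cross forces a unique genotype;
    sequenced calls are never overwritten, but one contradicting a forced
    expectation is flagged ``mendelian_conflict`` (and kept).
    """
    out = dict(calls)
    for _, row in pedigree.iterrows():
        fid = str(row["female_id"])
        forced = forced_offspring(str(row["dam_genotype"]),
                                  str(row["sire_genotype"]))
        if fid in out:
            call = out[fid]
            if (forced is not None and call.evidence == "sequenced"
                    and call.genotype not in (forced, "UNRESOLVED")):
                call.flags.add("mendelian_conflict")
            continue
        if forced is not None:
            out[fid] = GenotypeCall(fid, forced, "pedigree_imputed")
    return out


def tally_genotypes(calls: dict, metadata: pd.DataFrame):
    """Contingency counts of genotype per species x rearing light.

    ``metadata`` columns: female_id, species, rearing_light.  Returns
    (counts DataFrame, list of female ids present in calls but absent
    from the metadata).
    """
    meta = metadata.set_index(metadata["female_id"].astype(str))
    rows, unjoined = [], []
    for fid, call in sorted(calls.items()):
        if fid not in meta.index:
            unjoined.append(fid)
            continue
        rows.append({"female_id": fid, "genotype": call.genotype,
                     "species": meta.loc[fid, "species"],
                     "rearing_light": meta.loc[fid, "rearing_light"]})
    if not rows:
        counts = pd.DataFrame(columns=["species", "rearing_light",
                                       "genotype", "n"])
        return counts, unjoined
    df = pd.DataFrame(rows)
    counts = (df.groupby(["species", "rearing_light", "genotype"])
                .size().rename("n").reset_index())
    return counts, unjoined


def calls_to_frame(calls: dict) -> pd.DataFrame:
    rows = []
    for fid, c in sorted(calls.items()):
        rows.append({"female_id": fid, "genotype": c.genotype,
                     "evidence": c.evidence,
                     "site_216": c.per_site.get(216, ""),
                     "site_230": c.per_site.get(230, ""),
                     "site_275": c.per_site.get(275, ""),
                     "flags": ";".join(sorted(c.flags))})
    return pd.DataFrame(rows, columns=["female_id", "genotype", "evidence",
                                       "site_216", "site_230", "site_275",
                                       "flags"])
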