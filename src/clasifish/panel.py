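"""Nested rRNA probe panel: probes, fluorophore barcodes, and specificity screening.

A combinatorial-labeling FISH panel identifies taxa by the *set* of fluorophores
a cell lights up with, not by a single channel.  Probes are nested by taxonomic
rank (domain -> class -> genus), so a genus-level cell is positive for its
genus, class, and domain probes simultaneously.  The default panel shipped here
targets the four dominant epiphyte groups of the bull-kelp (*Nereocystis
luetkeana*) blade surface: *Granulosicoccus* (Gammaproteobacteria),
*Alphaproteobacteria*, *Bacteroidetes*, and *Verrucomicrobia*/*Planctomycetes*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ProbeDef",
    "ProbePanel",
    "SpecificityRule",
    "decode_barcode",
    "probe_mismatches",
    "screen_probe",
    "default_panel",
    "load_panel",
    "save_panel",
    "read_fasta",
    "BACKGROUND",
    "UNIDENTIFIED",
]

BACKGROUND = "background"
UNIDENTIFIED = "unidentified_bacterium"

_DNA_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class ProbeDef:
    """One oligonucleotide probe: name, target taxon, 5'->3' sequence, dye."""

    name: str
    target_taxon: str
    sequence: str
    fluorophore: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"probe {self.name}: empty sequence")
        bad = set(self.sequence.upper()) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"probe {self.name}: non-ACGT characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProbePanel:
    """A probe set plus the taxon -> fluorophore-combination barcode table.

    ``dye_list`` is ordered and defines the channel order of every unmixed
    image stack downstream.  Barcodes are frozensets of dye labels; they must
    be unique, non-empty, and drawn from ``dye_list``.
    """

    probes: list[ProbeDef]
    barcodes: dict[str, frozenset[str]]
    dye_list: list[str]

    def __post_init__(self) -> None:
        self.barcodes = {t: frozenset(b) for t, b in self.barcodes.items()}
        dyes = set(self.dye_list)
        if len(self.dye_list) != len(dyes):
            raise ValueError("dye_list contains duplicates")
        for probe in self.probes:
            if probe.fluorophore not in dyes:
                raise ValueError(
                    f"probe {probe.name}: fluorophore {probe.fluorophore!r} "
                    "not in dye_list"
                )
        seen: dict[frozenset[str], str] = {}
        for taxon, code in self.barcodes.items():
            if not code:
                raise ValueError(f"taxon {taxon}: empty barcode")
            if not code <= dyes:
                raise ValueError(
                    f"taxon {taxon}: barcode uses dyes outside dye_list: "
                    f"{sorted(code - dyes)}"
                )
            if code in seen:
                raise ValueError(
                    f"barcode {sorted(code)} assigned to both "
                    f"{seen[code]} and {taxon}"
                )
            seen[code] = taxon

    @property
    def taxa(self) -> list[str]:
        return list(self.barcodes)

    def leaf_taxa(self) -> list[str]:
        """Taxa whose barcode is not nested inside any other barcode.

        These are the most specific identifications the panel can make (the
        quantified groups); internal ranks like a class whose barcode is a
        subset of a genus barcode are not leaves.
        """
        return [
            t
            for t, code in self.barcodes.items()
            if not any(code < other for other in self.barcodes.values())
        ]

    def dye_for_probe(self, name: str) -> str:
        for probe in self.probes:
            if probe.name == name:
                return probe.fluorophore
        raise KeyError(name)

    def taxon_channel(self, taxon: str) -> str:
        """The taxon-specific dye: the barcode dye unique to this taxon.

        For a nested panel this is the most specific probe's fluorophore —
        the dye in this taxon's barcode that appears in no other taxon's
        barcode.  Internal ranks whose dyes are all shared (e.g. a class
        containing a barcoded genus) have no taxon channel.
        """
        code = self.barcodes[taxon]
        others: set[str] = set()
        for t, b in self.barcodes.items():
            if t != taxon:
                others |= b
        specific = code - others
        if not specific:
            raise ValueError(f"taxon {taxon}: no taxon-specific dye")
        # deterministic: first in channel order
        for dye in self.dye_list:
            if dye in specific:
                return dye
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class SpecificityRule:
    """Probe acceptance rule: perfect target match, >=2 mismatches off-target.

    ``max_target_mismatch_fraction`` tolerates a fraction of target sequences
    with imperfect matches ("most or all" coverage); default 0.0 = all targets
    must match perfectly.
    """

    min_offtarget_mismatches: int = 2
    require_perfect_target_match: bool = True
    max_target_mismatch_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.min_offtarget_mismatches < 1:
            raise ValueError("min_offtarget_mismatches must be >= 1")
        if not 0.0 <= self.max_target_mismatch_fraction <= 1.0:
            raise ValueError("max_target_mismatch_fraction must be in [0, 1]")


def decode_barcode(
    positive_fluorophores: set[str] | frozenset[str], panel: ProbePanel
) -> str:
    """Decode a set of positive dyes to a taxon label.

    The nested design means a cell's positive set should *contain* its
    taxon's barcode; the decoded taxon is the one with the largest barcode
    contained in the positive set (genus beats class beats domain).  An empty
    set is background; a positive set matching no barcode (e.g. the
    near-universal domain probe alone) is an unidentified bacterium.
    """
    positives = frozenset(positive_fluorophores)
    unknown = positives - set(panel.dye_list)
    if unknown:
        raise ValueError(f"dyes not in panel dye_list: {sorted(unknown)}")
    if not positives:
        return BACKGROUND
    candidates = [
        (len(code), taxon)
        for taxon, code in panel.barcodes.items()
        if code <= positives
    ]
    if not candidates:
        return UNIDENTIFIED
    candidates.sort(key=lambda c: (-c[0], c[1]))
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        # two equally specific barcodes both contained: not resolvable
        return UNIDENTIFIED
    return candidates[0][1]


def probe_mismatches(probe: ProbeDef, target_seq: str) -> int:
    """Minimum Hamming distance of the probe's binding site over the target.

    FISH probes are antisense to the rRNA, so the probe's reverse complement
    is slid (ungapped) along the sense-strand target; the minimum mismatch
    count over all offsets is returned.
    """
    target = target_seq.upper()
    binding = str(Seq(probe.sequence).reverse_complement())
    n, m = len(target), len(binding)
    if n < m:
        raise ValueError(
            f"target ({n} nt) shorter than probe {probe.name} ({m} nt)"
        )
    best = m
    for off in range(n - m + 1):
        window = target[off : off + m]
        mm = sum(a != b for a, b in zip(binding, window))
        if mm < best:
            best = mm
            if best == 0:
                break
    return best


def screen_probe(
    probe: ProbeDef,
    targets: list[str],
    offtargets: list[str],
    rule: SpecificityRule = SpecificityRule(),
) -> tuple[bool, "pd.DataFrame"]:
    """Screen a candidate probe for specificity against reference sequences.

    Passes when the probe matches its targets perfectly (up to the rule's
    tolerated fraction) and carries at least ``min_offtarget_mismatches``
    against every off-target sequence.  Returns (pass, per-sequence table).
    """
    import pandas as pd

    if not targets or not offtargets:
        raise ValueError("targets and offtargets must both be non-empty")
    rows = []
    for i, seq in enumerate(targets):
        rows.append(
            {"role": "target", "index": i, "mismatches": probe_mismatches(probe, seq)}
        )
    for i, seq in enumerate(offtargets):
        rows.append(
            {"role": "offtarget", "index": i, "mismatches": probe_mismatches(probe, seq)}
        )
    table = pd.DataFrame(rows)
    tgt = table[table.role == "target"].mismatches
    off = table[table.role == "offtarget"].mismatches
    ok_targets = True
    if rule.require_perfect_target_match:
        frac_bad = float((tgt > 0).mean())
        ok_targets = frac_bad <= rule.max_target_mismatch_fraction
    ok_off = bool((off >= rule.min_offtarget_mismatches).all())
    return ok_targets and ok_off, table


# ---------------------------------------------------------------------------
# Default kelp-surface panel (nested barcodes, 6 dyes, 7 probes + Gran670)

_DEFAULT_DYES = [
    "Atto532",        # Eub338-I, near-universal Bacteria
    "Dy415",          # Eub338-II + Eub338-III (shared by design)
    "Dy490",          # Alf968
    "Cy5",            # Gam42a
    "RhodamineRedX",  # Bac1058
    "TexasRedX",      # Gran737 / Gran670
]

_DEFAULT_PROBES = [
    ("Eub338-I", "Bacteria", "GCTGCCTCCCGTAGGAGT", "Atto532"),
    ("Eub338-II", "Planctomycetes", "GCAGCCACCCGTAGGTGT", "Dy415"),
    ("Eub338-III", "Verrucomicrobia", "GCTGCCACCCGTAGGTGT", "Dy415"),
    ("Alf968", "Alphaproteobacteria", "GGTAAGGTTCTGCGCGTT", "Dy490"),
    ("Gam42a", "Gammaproteobacteria", "GCCTTCCCACATCGTTT", "Cy5"),
    ("Bac1058", "Bacteroidetes", "TGAATGGCTGCTTCCAAGCCAACA", "RhodamineRedX"),
    ("Gran737", "Granulosicoccus", "TCAGCGTCAGTATTGTTCCAGA", "TexasRedX"),
    ("Gran670", "Granulosicoccus", "CACCGCTACACCCGGAATTCCGC", "TexasRedX"),
]

_DEFAULT_BARCODES = {
    "Granulosicoccus": {"Atto532", "Cy5", "TexasRedX"},
    "Gammaproteobacteria": {"Atto532", "Cy5"},
    "Alphaproteobacteria": {"Atto532", "Dy490"},
    "Bacteroidetes": {"Atto532", "RhodamineRedX"},
    "Verrucomicrobia/Planctomycetes": {"Dy415"},
}


def default_panel() -> ProbePanel:
    """The shipped kelp-surface panel with a concrete dye assignment.

    Where the published panel lists alternative dyes, this default fixes one
    per probe so that no dye is reused: Atto532 for Eub338-I and Dy490 for
    Alf968.
    """
    probes = [ProbeDef(*p) for p in _DEFAULT_PROBES]
    return ProbePanel(
        probes=probes,
        barcodes={t: frozenset(b) for t, b in _DEFAULT_BARCODES.items()},
        dye_list=list(_DEFAULT_DYES),
    )


def load_panel(path) -> ProbePanel:
    """Load a panel from a YAML config (dyes, probes, barcodes)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    probes = [
        ProbeDef(p["name"], p["target"], p["sequence"], p["dye"])
        for p in cfg["probes"]
    ]
    barcodes = {t: frozenset(d) for t, d in cfg["barcodes"].items()}
    return ProbePanel(probes=probes, barcodes=barcodes, dye_list=list(cfg["dyes"]))


def save_panel(panel: ProbePanel, path) -> None:
    cfg = {
        "dyes": list(panel.dye_list),
        "probes": [
            {
                "name": p.name,
                "target": p.target_taxon,
                "sequence": p.sequence,
                "dye": p.fluorophore,
            }
            for p in panel.probes
        ],
        "barcodes": {t: sorted(b) for t, b in panel.barcodes.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_fasta(path) -> dict[str, str]:
    """Read reference/probe sequences from FASTA as {id: sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
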