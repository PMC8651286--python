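"""Targeted amplicon panel: marker loci, CpG structure, calling rules.

Amplicon coordinates are 0-based half-open internally (BED convention);
reports use 1-based positions. Sequences are stored in read orientation on
the sequenced strand; reverse-complement handling lives in read assignment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .constants import AMPLICON_LENGTH_ADVISORY

#: IUPAC code standing for C-or-T at a CpG cytosine in a converted reference.
CPG_WILDCARD = "Y"

STRICT = "strict"
ALLOW_ONE = "allow_one_exception"


@dataclass(frozen=True)
class AmpliconDef:
    """One marker locus.

    ``cpg_offsets`` are 0-based positions of CpG cytosines within
    ``ref_seq``. ``unmeth_rule`` is ``"strict"`` (every CpG must read
    unmethylated) or ``"allow_one_exception"`` (at most one CpG may deviate;
    if ``exempt_cpgs`` is non-empty the deviation must be at a listed
    index).
    """

    name: str
    cell_type: str
    chrom: str
    start: int
    end: int
    ref_seq: str
    cpg_offsets: tuple[int, ...] = ()
    unmeth_rule: str = STRICT
    exempt_cpgs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        seq = self.ref_seq.upper()
        object.__setattr__(self, "ref_seq", seq)
        if set(seq) - set("ACGT"):
            raise ValueError(f"{self.name}: ref_seq has non-ACGT characters")
        if len(seq) != self.end - self.start:
            raise ValueError(
                f"{self.name}: length(ref_seq)={len(seq)} != end-start="
                f"{self.end - self.start}")
        offsets = self.cpg_offsets or tuple(find_cpg_offsets(seq))
        object.__setattr__(self, "cpg_offsets", tuple(offsets))
        if not self.cpg_offsets:
            raise ValueError(f"{self.name}: amplicon has no CpG site")
        if list(self.cpg_offsets) != sorted(set(self.cpg_offsets)):
            raise ValueError(f"{self.name}: cpg_offsets not strictly increasing")
        for o in self.cpg_offsets:
            if seq[o:o + 2] != "CG":
                raise ValueError(
                    f"{self.name}: offset {o} does not point at 'CG'")
        if self.unmeth_rule not in (STRICT, ALLOW_ONE):
            raise ValueError(f"{self.name}: unknown unmeth_rule "
                             f"{self.unmeth_rule!r}")
        if len(seq) > AMPLICON_LENGTH_ADVISORY:
            warnings.warn(
                f"{self.name}: length {len(seq)} bp exceeds the "
                f"{AMPLICON_LENGTH_ADVISORY} bp design bound", stacklevel=2)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)

    @property
    def non_cpg_c_offsets(self) -> tuple[int, ...]:
        """Positions of cytosines outside CpG context (conversion QC sites)."""
        cpg = set(self.cpg_offsets)
        return tuple(i for i, b in enumerate(self.ref_seq)
                     if b == "C" and i not in cpg)


def find_cpg_offsets(seq: str) -> list[int]:
    return [i for i in range(len(seq) - 1) if seq[i:i + 2] == "CG"]


def bisulfite_reference(amplicon: AmpliconDef) -> str:
    """Converted reference: non-CpG C -> T, CpG C -> Y (matches C or T)."""
    out = list(amplicon.ref_seq)
    cpg = set(amplicon.cpg_offsets)
    for i, b in enumerate(out):
        if b == "C":
            out[i] = CPG_WILDCARD if i in cpg else "T"
    return "".join(out)


@dataclass
class Panel:
    amplicons: list[AmpliconDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.amplicons]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate amplicon name: {dup}")

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons)

    def get(self, name: str) -> AmpliconDef:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def cell_type_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for a in self.amplicons:
            groups.setdefault(a.cell_type, []).append(a.name)
        return groups

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.cell_type_groups)


def load_panel(table_path: str | Path, fasta_path: str | Path) -> Panel:
    """Build a Panel from a BED-like TSV plus a FASTA of amplicon sequences.

    TSV columns: name, cell_type, chrom, start, end, unmeth_rule
    (optional, default strict), exempt_cpgs (optional comma list),
    cpg_offsets (optional comma list; auto-detected from the sequence when
    absent).
    """
    import pandas as pd

    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(table_path, sep="\t")
    amplicons = []
    for _, row in df.iterrows():
        name = str(row["name"])
        if name not in seqs:
            raise ValueError(f"FASTA record missing for marker {name}")
        offsets: tuple[int, ...] = ()
        if "cpg_offsets" in df.columns and pd.notna(row.get("cpg_offsets")):
            offsets = tuple(int(x) for x in str(row["cpg_offsets"]).split(","))
        exempt: tuple[int, ...] = ()
        if "exempt_cpgs" in df.columns and pd.notna(row.get("exempt_cpgs")):
            exempt = tuple(int(x) for x in str(row["exempt_cpgs"]).split(","))
        rule = STRICT
        if "unmeth_rule" in df.columns and pd.notna(row.get("unmeth_rule")):
            rule = str(row["unmeth_rule"])
        amplicons.append(AmpliconDef(
            name=name, cell_type=str(row["cell_type"]),
            chrom=str(row["chrom"]), start=int(row["start"]),
            end=int(row["end"]), ref_seq=seqs[name],
            cpg_offsets=offsets, unmeth_rule=rule, exempt_cpgs=exempt))
    return Panel(amplicons=amplicons)


def write_panel(panel: Panel, table_path: str | Path,
                fasta_path: str | Path) -> None:
    import pandas as pd

    rows = []
    for a in panel:
        rows.append({
            "name": a.name, "cell_type": a.cell_type, "chrom": a.chrom,
            "start": a.start, "end": a.end, "unmeth_rule": a.unmeth_rule,
            "exempt_cpgs": ",".join(map(str, a.exempt_cpgs)) or None,
            "cpg_offsets": ",".join(map(str, a.cpg_offsets)),
        })
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for a in panel:
            fh.write(f">{a.name}\n{a.ref_seq}\n")


def _wildcard_identity(a: str, b: str) -> float:
    """Percent of positions where two converted references can match."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    ct = set("CT")
    hits = 0
    for x, y in zip(a[:n], b[:n]):
        if x == y:
            hits += 1
        elif x == CPG_WILDCARD and y in ct:
            hits += 1
        elif y == CPG_WILDCARD and x in ct:
            hits += 1
    return 100.0 * hits / max(len(a), len(b))


def validate_panel(panel: Panel) -> dict:
    """Report-only diagnostics: CpG counts, length warnings, cross-amplicon
    similarity of converted references."""
    if len(panel) == 0:
        raise ValueError("empty panel")
    markers = {}
    for a in panel:
        markers[a.name] = {
            "cell_type": a.cell_type,
            "length": len(a.ref_seq),
            "n_cpgs": a.n_cpgs,
            "n_non_cpg_c": len(a.non_cpg_c_offsets),
            "length_warning": len(a.ref_seq) > AMPLICON_LENGTH_ADVISORY,
            "unmeth_rule": a.unmeth_rule,
        }
    ambiguous = []
    similar = []
    for a, b in itertools.combinations(panel, 2):
        ra, rb = bisulfite_reference(a), bisulfite_reference(b)
        ident = _wildcard_identity(ra, rb)
        if ra == rb:
            ambiguous.append((a.name, b.name))
        elif ident > 80.0:  # < 20% divergence
            similar.append((a.name, b.name, round(ident, 1)))
    return {
        "n_markers": len(panel),
        "cell_type_groups": panel.cell_type_groups,
        "markers": markers,
        "ambiguous_pairs": ambiguous,
        "similar_pairs": similar,
    }


def default_panel(seed: int = 20210201) -> Panel:
    """The 16-marker / 7-cell-type reference panel fixture.

    Marker names follow the published cocktail (three neutrophil, two
    monocyte, two eosinophil, three B-cell, two T-cell, two CD8 and two
    Treg markers). Sequences are synthetic stand-ins generated
    deterministically: the assay's genomic sequences are not redistributed
    here, only the panel's structure.
    """
    import numpy as np

    spec: list[tuple[str, str, int]] = [
        ("NEUT1", "neutrophil", 5), ("NEUT2", "neutrophil", 4),
        ("NEUT3", "neutrophil", 6), ("MONO1", "monocyte", 5),
        ("MONO2", "monocyte", 4), ("EOSI2", "eosinophil", 5),
        ("EOSI3", "eosinophil", 6), ("B-CELL1", "b_cell", 5),
        ("B-CELL2", "b_cell", 4), ("B-CELL3", "b_cell", 5),
        ("T-CELL1", "t_cell", 4), ("T-CELL2", "t_cell", 5),
        ("CD8A", "cd8_t_cell", 4), ("CD8B", "cd8_t_cell", 5),
        ("TREG1", "treg", 4), ("TREG2", "treg", 5),
    ]
    rng = np.random.default_rng(seed)
    amplicons = []
    for i, (name, cell_type, n_cpgs) in enumerate(spec):
        length = 120  # uniform length keeps batch assignment single-offset
        # backbone over {A,G,T}; CpGs and lone (non-CpG) Cs planted explicitly
        seq = list(rng.choice(list("AGT"), size=length))
        positions = np.linspace(8, length - 10, n_cpgs).astype(int)
        for p in positions:
            seq[p], seq[p + 1] = "C", "G"
        # non-CpG cytosines for conversion QC: C followed by A or T
        qc_sites = rng.choice(
            [j for j in range(4, length - 4)
             if all(abs(j - p) > 2 for p in positions)],
            size=8, replace=False)
        for j in qc_sites:
            seq[j] = "C"
            if seq[j + 1] == "G":
                seq[j + 1] = "A"
        start = 1_000_000 * (i + 1)
        amplicons.append(AmpliconDef(
            name=name, cell_type=cell_type, chrom=f"chr{(i % 9) + 1}",
            start=start, end=start + length, ref_seq="".join(seq),
            unmeth_rule=ALLOW_ONE if name in ("NEUT3", "B-CELL3") else STRICT))
    return Panel(amplicons=amplicons)
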