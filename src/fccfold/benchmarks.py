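"""Benchmark HP sequences (data sets I-IV) and amino-acid -> HP encoding.

Data set I: eight classic HP sequences of 20-64 residues.  Data set II:
ten 48-residue sequences from the 3D-cube benchmark literature.  Data set
III: fifteen long sequences (90-200 residues).  Data set IV: five real
protein sequences (PDB ids) with their HP transforms.  ``reference_optimum``
is the known optimal HH-contact count on the FCC lattice where one has
been established by exact (constraint-programming) methods; it is None
where no optimum is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .conformation import validate_hp_sequence

#: Hydrophobic residues for the default amino-acid -> H mapping.  The set
#: includes tyrosine: it is the unique single-residue classification that
#: reproduces the data-set-IV HP transforms exactly.
DEFAULT_HYDROPHOBIC_SET = frozenset("CFILMVWY")


class UnknownDatasetError(KeyError):
    pass


@dataclass(frozen=True)
class BenchmarkRecord:
    dataset: str
    name: str
    length: int
    hp_sequence: str
    reference_optimum: Optional[int] = None
    aa_sequence: Optional[str] = None
    #: Suggested EA generation budget for this chain (benchmark settings).
    iterations: int = 30
    population_size: int = 10


def hp_encode(aa_sequence: str, hydrophobic_set=DEFAULT_HYDROPHOBIC_SET,
              strict: bool = True) -> str:
    """Map a one-letter amino-acid string to an HP string.

    Residues in ``hydrophobic_set`` become H, all others P.  With
    ``strict``, letters outside the 20 standard codes raise; otherwise
    they pass through as P.
    """
    aa_sequence = aa_sequence.replace(" ", "").upper()
    standard = set("ACDEFGHIKLMNPQRSTVWY")
    out = []
    for ch in aa_sequence:
        if ch not in standard:
            if strict:
                raise ValueError(f"unknown amino-acid code {ch!r}")
            out.append("P")
            continue
        out.append("H" if ch in hydrophobic_set else "P")
    return "".join(out)


def _rec(dataset, name, seq, opt=None, aa=None, iterations=30, pop=10):
    seq = validate_hp_sequence(seq)
    return BenchmarkRecord(
        dataset=dataset,
        name=name,
        length=len(seq),
        hp_sequence=seq,
        reference_optimum=opt,
        aa_sequence=aa,
        iterations=iterations,
        population_size=pop,
    )


DATASET_I: tuple[BenchmarkRecord, ...] = (
    _rec("I", "S1", "HPHPPHHPHPPHPHHPPHPH", 23, iterations=30),
    _rec("I", "S2", "HHPPHPPHPPHPPHPPHPPHPPHH", 23, iterations=30),
    _rec("I", "S3", "PPHPPHHPPPPHHPPPPHHPPPPHH", 17, iterations=30),
    _rec("I", "S4", "PPPHHPPHHPPPPPHHHHHHHPPHHPPPPHHPPHPP", 38, iterations=30),
    _rec("I", "S5", "PPHPHHHPHHHPPPPPHHHHHHHHHHPPPPPPHHPPHHPPHPPHHHHH", 74, iterations=30),
    _rec("I", "S6", "HHPHPHPHPHHHHPHPPPHPPPHPPPPHPPPHPPPHPHHHHPHPHPHPHH", 73, iterations=100),
    _rec("I", "S7",
         "PPHHHPHHHHHHHHPPPHHHHHHHHHHPHPPPHHHHHHHHHHHHPPPPHHHHHHPHHPHH",
         130, iterations=100),
    _rec("I", "S8",
         "HHHHHHHHHHHHPHPHPPHHPPHHPPHPPHHPPHHPPHPPHHPPHHPPHPHPHHHHHHHHHHHH",
         132, iterations=150),
)

_DATASET_II_OPTIMA = (69, 69, 72, 71, 70, 70, 70, 69, 71, 68)
_DATASET_II_SEQS = (
    "HPHHPPHHHHPHHHPPHHPPHPHHHPHPHHPPHHPPPHPPPPPPPPHH",
    "HHHHPHHPHHHHHPPHPPHHPPHPPPPPPHPPHPPPHPPHHPPHHHPH",
    "PHPHHPHHHHHHPPHPHPPHPHHPHPHPPPHPPHHPPHHPPHPHPPHP",
    "PHPHHPPHPHHHPPHHPHHPPPHHHHHPPHPHHPHPHPPPPHPPHPHP",
    "PPHPPPHPHHHHPPHHHHPHHPHHHPPHPHPHPPHPPPPPPHHPHHPH",
    "HHHPPPHHPHPHHPHHPHHPHPPPPPPPHPHPPHPPPHPPHHHHHHPH",
    "PHPPPPHPHHHPHPHHHHPHHPHHPPPHPHPPPHHHPPHHPPHHPPPH",
    "PHHPHHHPHHHHPPHHHPPPPPPHPHHPPHHPHPPPHHPHPHPHHPPP",
    "PHPHPPPPHPHPHPPHPHHHHHHPPHHHPHPPHPHHPPHPHHHPPPPH",
    "PHHPPPPPPHHPPPHHHPHPPHPHHPPHPPHPPHHPPHHHHHHHPPHH",
)

DATASET_II: tuple[BenchmarkRecord, ...] = tuple(
    _rec("II", f"H{i + 1}", seq, opt, iterations=150, pop=40)
    for i, (seq, opt) in enumerate(zip(_DATASET_II_SEQS, _DATASET_II_OPTIMA))
)

DATASET_III: tuple[BenchmarkRecord, ...] = (
    _rec("III", "F90_1",
         "PPHHHPPPHHPPPPHHPHHHHHHPHPHPHHPHHHHHPHHHPHPHHHHPHHPPPPHHHPHPHPPHHHPHHPHPHPPHHHPPPPHHPPHPPP",
         168, iterations=150, pop=40),
    _rec("III", "F90_2",
         "PHHPPHPHHPHHHPHHHPPHHHHHHPPHPHPPPPHHHPHPPHHHHPHHHHPHHHPHHPPPPPHHPPPPHPHPHPHPHHPPHHHPPPHHHP",
         168, iterations=150, pop=40),
    _rec("III", "F90_3",
         "HPHPHHHPHHHHPHHHPPPHPPPHPPPPHHHPPHPPPPHHHPPPPPPPPHPHHPHHHHPHHHPHPHHPPHHHHHPHHPPHHPHHHHHHPH",
         167, iterations=150, pop=40),
    _rec("III", "F90_4",
         "PHHHPPHPPHPHPPPPHPPPHPHPPHPHHPHPPPHHHPHHHPPHHHPPHPPPPHPHHHPPHHPPHHHPPHHHHHHPHHHHHHHPHHHHPH",
         168, iterations=150, pop=40),
    _rec("III", "F90_5",
         "PPPHPHHHHHHHPPPHPPHHHHHPHHPPHHPPHHHHPHPHPHHPPHHPPPPHPPPHHHPHPHHHHHHHPHHPHPPHHPPPHHHPHPPHPP",
         167, iterations=150, pop=40),
    _rec("III", "S1",
         "HHHHPHHHHHHPPHHPHHHHHHHHPHHPHHHHHHHHHHPPHHPPPPPHHPHHHHHHHHPHPPHHPPPHHHHHHHHPHHHHHHPPHHHHHHHPHPPHHHHHHHHHPPHHPPPHHHHHHHPHHPHHHHHHHPPHHHH",
         357, iterations=150, pop=40),
    _rec("III", "S2",
         "HHPPHPHHHHHHHHHHPHPPPPHHHPPPHHHHHPPHHHHHPPHHHHPPHHHHPPHHHHHHPHHHHPPPHHPPPHHHHHHHHPHPPHHHPPPHHHHHPPHHHHHHHPPPHHPPHHHHHPPPHHHHHHHHHPHPPHHHHHHHPPPHHHPPHHP",
         360, iterations=150, pop=40),
    _rec("III", "S3",
         "HHHPPPHHPHHPPPPPHHHHHHHHPHPPHHPHHPHHHHHPPPHHHHHHHHHPPHPHPPHPHPPHHHPHPPHPHPPPHHHHHHPHHHHPPPHHHPPPPHHPPPHHHPPHHHHPHHHHHPPHHHHHHPPPHHHHHHPPPHPPHHHHPHHHHHHHPPHHPPHHH",
         367, iterations=150, pop=40),
    _rec("III", "S4",
         "HHPPHPHHHHHHHPPHPHPPHPHPPPPHHHPPPHHPHPHHPPHHHHHPPHHHHPPHHHHPPHHHHHHPHHHHPPPHHPPPHHHHHHHHPHPPHHHPPPHHHHHPPHHHHHHPHPPPHHPPHHHPHHPPPHPHHHHHHHPHPPHPPHHHHHHPHPPPHHHPPHHP",
         370, iterations=150, pop=40),
    _rec("III", "R1",
         "PPPHPHHPHHPPPHPHPPPPHPHHPPHPHHHHHPPHHPPHHHHHHPPHPPHHPPHPHPHHHHHPHHPHHHPPPHHHPHHPPHPHPPHPPPHPPHPPHPPHHHPHHHPHPPHPHHPHHHHPHPHHHPHHHPPPPPPHHHHHHPPPPPPPPHHHPPHPHPPPHPHPHPHHPPHHPPPPHHHHHHPPPHHPPPPPHPPPHHPP",
         384, iterations=150, pop=40),
    _rec("III", "R2",
         "HPHHPPHPPPPPHHPHPHPHHPPHPPPPHHHHHHPPPHPPHHHPPHPPPPHHPPHHHPHPHHHPPHPHHPPHPHHPPPPHHPPHPPHHHHPPPPPHHHPPPPHPPPPPPHPPHHPHHHHPHHHHHHHHPPHHPPPHPHHHPHHHHHPHHPHHHPHPHHPPPPHPHHPHHHPHPPPPHPPPPPPHPHHHHHPHHPPPHPPH",
         383, iterations=150, pop=40),
    _rec("III", "R3",
         "HPHHHPHHPHPHPPPHHHHHPHPHPHHHHPPPHHPPPPPPHHPPPPHPHHHPPPPHPPPHHPHHPPPHPPHPPPHHHHPHHPHPPPPHHPPPHHPPHPPPHPPHHHPHHHPHPPHPHHHHPPHHPPPPHHHPHHPPHPPHHHHPPHPHPPHPHPPPPPHPHPHHHHHHHPHPHHHHHHPHHPPPPHPPPPHPPPHHHPHH",
         385, iterations=150, pop=40),
    _rec("III", "F180_1",
         "HHPPHHHHHPHHHPPPHHHPPHHHPHPPHHHHHPPPHHHPPPHPHHPPPPPHHPPHHPHHPHPHHPPPPPHHHPPPPHPHHHPPHPPPHHHPHHHHPPHHPHPHHHHPHHHHPPHHPHHPHHPHHHPHPPHPHHPHPHHPHHHPHHPPHPPPHPPPPPPPHHHPHHHHHPHHHHHPPHPP",
         None, iterations=150, pop=40),
    _rec("III", "F180_2",
         "PHHPHPPPHPPHHPHHHPHPHHPHHHPHHHPPPHHPPHPHPHHPHHHHPPHHPHPHHHHHPHHPPPPHPHPHPPHHHHPHHHHPHHHHHPPHPHHHPPPHPHPPHHPPPHHPHPHPPPPPHPHHPHHHPHPPPPHHPHHHHHPPPHHHHHHHHPHHPPPPPHPPPHPPHPPPHHPHHHHH",
         None, iterations=150, pop=40),
    _rec("III", "F180_3",
         "HHHPHPPHHPPPHPPPHPHPHPPHHHHPPHHHHHHPHPHHPPPPPHPPHHPHHHHHHHHHHHPPHPPHPPHHHHHHHHPPPPHPPHHHHHPPHHHPPHHPPHHHHHPPPHHHHHHPHHHPPPHHPPHPPPHPPHPPPHPPPPHHHPPHHPHPPHHHPHHPPHHPHHPHPHPHPHPHPHHP",
         378, iterations=150, pop=40),
)

_DATASET_IV_AA = {
    "4BP2": "ALWQFNGMIKCKIPSSEPLLDFNNYGCYCGLGGSGTPVDDLDRCCQTHDNCYKQAKKLDSCKVLVDNPYTNNYSYSCSNNEITCSSENNACEAFICNCDRNAAICFSKVPYNKEHKNLDKKNC",
    "2AAS": "KETAAAKFERQHMDSSTSAASSSNYCNQMMKSRNLTKDRCKPVNTFVHESLADVQAVCSQKNVACKNGQTNCYQSYSTMSITDCRETGSSKYPNCAYKTTQANKHIIVACEGNPYVPVHFDASV",
    "5LYZ": "KVFGRCELAAAMKRHGLDNYRGYSLGNWVCAAKFESNFNTQATNRNTDGSTDYGILQINSRWWCNDGRTPGSRNLCNIPCSALLSSDITASVNCAKKIVSDGNGMNAWVAWRNRCKGTDVQAWIRGCRL",
    "9WGA": "RCGEQGSNMECPNNLCCSQYGYCGMGGDYCGKGCQNGACWTSKRCGSQAGGATCPNNHCCSQYGHCGFGAEYCGAGCQGGPCRADIKCGSQSGGKLCPNNLCCSQWGFCGLGSEFCGGGCQSGACSTDKPCGKDAGGRVCTNNYCCSKWGSCGIGPGYCGAGCQSGGCDA",
    "1RBP": "ERDCRVSSFRVKENFDKARFSGTWYAMAKKDPEGLFLQDNIVAEFSVDETGQMSATAKGRVRLLNNWDVCADMVGTFTDTEDPAKFKMKYWGVASFLQKGNDDHWIVDTDYDTYAVQYSCRLLNLDGTCADSYSFVFSRDPNGLPPEAQKIVRQRQEELCLARQYRLIVHNGYC",
}

DATASET_IV: tuple[BenchmarkRecord, ...] = tuple(
    _rec("IV", name, hp_encode(aa), None, aa=aa, iterations=150, pop=40)
    for name, aa in _DATASET_IV_AA.items()
)

_DATASETS: dict[str, tuple[BenchmarkRecord, ...]] = {
    "I": DATASET_I,
    "II": DATASET_II,
    "III": DATASET_III,
    "IV": DATASET_IV,
}


def load_benchmarks(dataset: str) -> list[BenchmarkRecord]:
    """Records of one data set ('I', 'II', 'III' or 'IV')."""
    try:
        return list(_DATASETS[dataset.upper()])
    except KeyError:
        raise UnknownDatasetError(
            f"unknown dataset {dataset!r}; expected one of I, II, III, IV"
        )


def get_benchmark(name: str, dataset: Optional[str] = None) -> BenchmarkRecord:
    """Look up a benchmark by name (dataset III reuses S1-S4; disambiguate)."""
    sets = [_DATASETS[dataset.upper()]] if dataset else _DATASETS.values()
    for records in sets:
        for rec in records:
            if rec.name == name:
                return rec
    raise UnknownDatasetError(f"no benchmark named {name!r}")
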