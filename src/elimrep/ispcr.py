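"""In-silico PCR on tandem-array templates: the monomer/multimer ladder.

A primer pair internal to a tandem monomer amplifies, from an array of that
monomer, a ladder of products whose sizes step by exactly one unit length -
the monomer, dimer, trimer ... bands seen on a gel. Matching here is purely
sequence-based (substitution mismatches up to a cap, with the five bases at
each primer's 3' end required to match exactly); no melting-temperature or
cycling thermodynamics are modelled.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from ._seq import revcomp

#: bands whose sizes differ by no more than this are collapsed into one
BAND_COLLAPSE_BP = 1

#: bases at the primer 3' end that must match exactly
ANCHOR_3P = 5


@dataclass(frozen=True)
class PrimerPair:
    """A primer pair, both sequences written 5'->3'."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            if not 15 <= len(p) <= 30:
                raise ValueError("primer length must be 15-30 nt")
            if set(p) - set("ACGT"):
                raise ValueError("primers must be A/C/G/T only")


@dataclass(frozen=True)
class Band:
    size: int
    fwd_site: int
    rev_site: int
    n_units_spanned: float | None = None


@dataclass
class AmpliconLadder:
    """Predicted product sizes, strictly increasing."""

    bands: list[Band]

    @property
    def band_sizes(self) -> list[int]:
        return [b.size for b in self.bands]

    def __len__(self) -> int:
        return len(self.bands)


def find_primer_sites(template: str, primer: str,
                      max_mismatch: int = 2) -> list[tuple[int, str]]:
    """All template positions where the primer anneals, on either strand.

    Plus-strand sites are positions where the primer matches the template
    with at most ``max_mismatch`` substitutions; minus-strand sites are
    matches of the reverse complement. The five 3'-terminal bases of the
    primer must match exactly (polymerase extension anchor). Returns
    (0-based window start, strand) sorted by position.
    """
    template, primer = template.upper(), primer.upper()
    if len(primer) > len(template):
        return []
    L = len(primer)
    rc = revcomp(primer)
    sites: list[tuple[int, str]] = []
    for i in range(len(template) - L + 1):
        win = template[i:i + L]
        # + strand: primer 3' end is the window's right edge
        if win[-ANCHOR_3P:] == primer[-ANCHOR_3P:]:
            mm = sum(a != b for a, b in zip(win, primer))
            if mm <= max_mismatch:
                sites.append((i, "+"))
        # - strand: primer 3' end maps to the window's left edge
        if win[:ANCHOR_3P] == rc[:ANCHOR_3P]:
            mm = sum(a != b for a, b in zip(win, rc))
            if mm <= max_mismatch:
                sites.append((i, "-"))
    return sites


def predict_amplicons(template: str, pair: PrimerPair, max_len: int = 3000,
                      max_mismatch: int = 2) -> AmpliconLadder:
    """Enumerate products of the pair on a template.

    A product needs a forward-primer site on the plus strand and a
    reverse-primer site on the minus strand with the reverse primer's 3'
    end downstream of the forward primer's 3' end; its size is the spanned
    distance. Sizes within BAND_COLLAPSE_BP collapse into one band.
    """
    if not template:
        raise ValueError("invalid-input: empty template")
    fwd_sites = [p for p, s in find_primer_sites(template, pair.forward, max_mismatch)
                 if s == "+"]
    rev_sites = [p for p, s in find_primer_sites(template, pair.reverse, max_mismatch)
                 if s == "-"]
    lenF, lenR = len(pair.forward), len(pair.reverse)
    raw: list[Band] = []
    for f in fwd_sites:
        for r in rev_sites:
            if r < f + lenF:
                continue  # reverse 3' end not downstream of forward 3' end
            size = r + lenR - f
            if size <= max_len:
                raw.append(Band(size, f, r))
    raw.sort(key=lambda b: (b.size, b.fwd_site))
    bands: list[Band] = []
    for b in raw:
        if bands and b.size - bands[-1].size <= BAND_COLLAPSE_BP:
            continue
        bands.append(b)
    return AmpliconLadder(bands)


_ORDINAL = {1: "monomer", 2: "dimer", 3: "trimer"}


def ladder_report(ladder: AmpliconLadder, unit_length: int,
                  tolerance: float = 0.10) -> list[dict]:
    """Label each band monomer/dimer/k-mer or flag it as a variant.

    A band of size s is labelled the k-mer rung when |s - k*unit| is within
    ``tolerance`` of k*unit; off-ladder bands (e.g. the extra germline bands
    a variant repeat unit produces) are flagged 'variant'.
    """
    if unit_length <= 0:
        raise ValueError("invalid-parameter: unit_length must be positive")
    out: list[dict] = []
    for b in ladder.bands:
        k = max(1, round(b.size / unit_length))
        if abs(b.size - k * unit_length) <= tolerance * k * unit_length:
            label = _ORDINAL.get(k, f"{k}-mer")
            n_units: float | None = float(k)
        else:
            label, n_units = "variant", None
        out.append(dict(band_bp=b.size, label=label, n_units=n_units,
                        fwd_site=b.fwd_site, rev_site=b.rev_site))
    return out


def render_gel(ladders: dict[str, AmpliconLadder], max_bp: int = 1500,
               height: int = 24) -> str:
    """Crude text-art gel: one lane per ladder, size decreasing downwards."""
    lanes = sorted(ladders)
    rows = []
    rows.append("bp    | " + " | ".join(f"{l:^10}" for l in lanes))
    for h in range(height):
        top = max_bp * (height - h) / height
        bot = max_bp * (height - h - 1) / height
        cells = []
        for l in lanes:
            hit = any(bot < b <= top for b in ladders[l].band_sizes)
            cells.append("▬▬▬▬▬▬".center(10) if hit else " " * 10)
        rows.append(f"{int(top):>5} | " + " | ".join(cells))
    return "\n".join(rows)


def load_primer_pairs(path: str | Path | None = None) -> dict[str, PrimerPair]:
    """Load primer pairs from TSV (name, forward, reverse).

    With no path, loads the packaged pair set for the four novel repeat
    families (units 360/47/84/120 bp).
    """
    import pandas as pd

    if path is None:
        with resources.files("elimrep.data").joinpath("primers.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return {str(r.name): PrimerPair(str(r.name), str(r.forward), str(r.reverse))
            for r in df.itertuples(index=False)}


def ladder_to_tsv(report: Sequence[dict], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(report).to_csv(path, sep="\t", index=False)
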