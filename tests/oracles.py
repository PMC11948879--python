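"""Independent reference implementations used only to check the package.

These deliberately share no code with methcohort: the decoder walks the
read one base at a time, the region filter is a linear scan, and the
CpG scan is a regex.
"""

from __future__ import annotations

import re


def naive_decode(seq, is_reverse, aligned_pairs, mm, ml):
    """Base-by-base MM/ML decoder. Returns {(ref_pos, code): prob}.

    Walks the sequenced-orientation read linearly, consuming skip-counts
    as canonical bases stream past; '.' runs emit probability-0 calls for
    every unlisted canonical base.
    """
    seq = seq.upper()
    length = len(seq)
    strand = "-" if is_reverse else "+"
    out = {}
    ml = list(ml)
    ml_i = 0
    for run in mm.rstrip(";").split(";"):
        if not run:
            continue
        head, _, tail = run.partition(",")
        base, mm_strand = head[0].upper(), head[1]
        assert mm_strand == "+"
        rest = head[2:]
        flag = "?" if rest.endswith("?") else "."
        codes = rest.rstrip(".?")
        deltas = [int(x) for x in tail.split(",")] if tail else []
        di = 0
        to_skip = deltas[0] if deltas else None
        for i, b in enumerate(seq):
            if base != "N" and b != base:
                continue
            listed_here = False
            if to_skip is not None:
                if to_skip == 0:
                    listed_here = True
                    di += 1
                    to_skip = deltas[di] if di < len(deltas) else None
                else:
                    to_skip -= 1
            for code in codes:
                if listed_here:
                    prob = (ml[ml_i] + 0.5) / 256.0
                    ml_i += 1
                elif flag == ".":
                    prob = 0.0
                else:
                    continue
                sam_i = length - 1 - i if is_reverse else i
                if sam_i in aligned_pairs:
                    out[(aligned_pairs[sam_i], code)] = (prob, strand)
    assert ml_i == len(ml)
    return out


def scan_region(table, chrom, start, end):
    """Linear-scan row filter over an in-memory table."""
    keep = [
        i
        for i, (c, p) in enumerate(table.sites)
        if c == chrom and start <= p <= end
    ]
    return [table.sites[i] for i in keep], table.data.to_numpy()[keep]


def regex_cpg(seq):
    return [m.start() + 1 for m in re.finditer("CG", seq.upper())]
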