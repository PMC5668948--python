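"""Generate the bundled synthetic ME consensus library and subfamily table."""
import random

LENS = {"ALU": 300, "LINE1": 6019, "SVA": 1316}
OUT_FA = "src/meikit/data/me_consensus.fa"
OUT_TSV = "src/meikit/data/subfamilies.tsv"

rng = random.Random(20240917)


def gen(n):
    # avoid homopolymer runs >= 6 so poly(A) logic stays unambiguous
    seq = []
    while len(seq) < n:
        b = rng.choice("ACGT")
        if len(seq) >= 5 and all(x == b for x in seq[-5:]):
            continue
        seq.append(b)
    return "".join(seq)


cons = {name: gen(n) for name, n in LENS.items()}

with open(OUT_FA, "w") as fh:
    for name, seq in cons.items():
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def cpg_positions(seq):
    pos = set()
    for i in range(len(seq) - 1):
        if seq[i : i + 2] == "CG":
            pos.add(i)
            pos.add(i + 1)
    return pos

ALT = {"A": "G", "C": "T", "G": "A", "T": "C"}


def pick_diag(seq, k, taken, lo, hi):
    out = []
    cpg = cpg_positions(seq)
    while len(out) < k:
        p = rng.randrange(lo, hi)
        if p in taken or p in cpg:
            continue
        taken.add(p)
        out.append((p, seq[p], ALT[seq[p]]))
    return sorted(out)

rows = []
taken_alu = set()
for sub, k in [("AluYa5", 5), ("AluYb8", 8)]:
    for p, r, a in pick_diag(cons["ALU"], k, taken_alu, 10, 290):
        rows.append(("ALU", sub, p, r, a))

# L1-Ta1d nests on top of L1-Ta: shares its 3 diagnostics plus 2 private ones
taken_l1 = set()
ta = pick_diag(cons["LINE1"], 3, taken_l1, 100, 6000)
ta1d = sorted(ta + pick_diag(cons["LINE1"], 2, taken_l1, 100, 6000))
for p, r, a in ta:
    rows.append(("LINE1", "L1-Ta", p, r, a))
for p, r, a in ta1d:
    rows.append(("LINE1", "L1-Ta1d", p, r, a))

with open(OUT_TSV, "w") as fh:
    fh.write("class\tsubfamily\tposition\tref\talt\n")
    for c, s, p, r, a in rows:
        fh.write(f"{c}\t{s}\t{p}\t{r}\t{a}\n")

print("wrote", OUT_FA, OUT_TSV)
for name, seq in cons.items():
    print(name, len(seq), "CpG:", len(cpg_positions(seq)))
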