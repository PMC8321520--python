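"""Paired test readers: parse writer output back into plain structures.

These are deliberately naive, line-oriented parsers kept independent of the
writer implementations so that write → read round-trips are a real check of
the emitted dialects.
"""

from __future__ import annotations


def read_ima(path):
    lines = open(path).read().splitlines()
    title = lines[0]
    n_pops = int(lines[1])
    pop_names = lines[2].split()
    tree = lines[3]
    n_loci = int(lines[4])
    loci = []
    i = 5
    for _ in range(n_loci):
        parts = lines[i].split()
        name = parts[0]
        counts = [int(x) for x in parts[1 : 1 + n_pops]]
        length = int(parts[1 + n_pops])
        mut_model = parts[2 + n_pops]
        inheritance = float(parts[3 + n_pops])
        i += 1
        seqs = []
        for _ in range(sum(counts)):
            seqs.append((lines[i][:10].rstrip(), lines[i][10:]))
            i += 1
        loci.append(
            {
                "name": name,
                "counts": counts,
                "length": length,
                "model": mut_model,
                "inheritance": inheritance,
                "sequences": seqs,
            }
        )
    assert i == len(lines), "trailing unparsed lines in IM file"
    return {"title": title, "pops": pop_names, "tree": tree, "loci": loci}


def read_gphocs(path):
    lines = open(path).read().splitlines()
    n_loci = int(lines[0])
    loci = []
    i = 1
    for _ in range(n_loci):
        name, n, length = lines[i].split()
        n, length = int(n), int(length)
        i += 1
        seqs = []
        for _ in range(n):
            seq_name, seq = lines[i].split()
            seqs.append((seq_name, seq))
            i += 1
        loci.append({"name": name, "n": n, "length": length, "sequences": seqs})
    assert i == len(lines)
    return loci


def read_treemix(path):
    lines = open(path).read().splitlines()
    pops = lines[0].split()
    rows = []
    for line in lines[1:]:
        row = []
        for cell in line.split():
            ref, alt = cell.split(",")
            row.append((int(ref), int(alt)))
        assert len(row) == len(pops)
        rows.append(row)
    return pops, rows


def read_eigenstrat(prefix):
    geno = [
        [int(d) for d in line.strip()] for line in open(f"{prefix}.geno") if line.strip()
    ]
    snp = [line.split("\t") for line in open(f"{prefix}.snp").read().splitlines()]
    ind = [line.split("\t") for line in open(f"{prefix}.ind").read().splitlines()]
    return geno, snp, ind


def read_ped(prefix):
    ped = [line.split("\t") for line in open(f"{prefix}.ped").read().splitlines()]
    ped_rows = []
    for row in ped:
        meta, alleles = row[:6], row[6:]
        pairs = [(alleles[2 * i], alleles[2 * i + 1]) for i in range(len(alleles) // 2)]
        ped_rows.append((meta, pairs))
    mp = [line.split("\t") for line in open(f"{prefix}.map").read().splitlines()]
    return ped_rows, mp


def read_dadi(path):
    lines = open(path).read().splitlines()
    header = lines[0].split("\t")
    rows = [line.split("\t") for line in lines[1:]]
    return header, rows
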