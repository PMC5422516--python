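#!/usr/bin/env python
"""Median-joining networks for each nuclear gene and the chloroplast system.

With monomorphic parental populations the per-gene networks are two parental
haplotype nodes joined through the hybrid's pair; the chloroplast network
separates the parental clusters by >= 14 mutational steps (every fixed
substitution plus fifth-state indel events counted once each).

Writes: results/networks/network_<locus>.{tsv,dot} and node tables.
"""

from pathlib import Path

from hybdiag.fixtures import CP_LOCI, NUCLEAR_LOCI, build_dataset
from hybdiag.network import export_network, node_table
from hybdiag.pipeline import RunConfig, diagnose, locus_network

OUT = Path(__file__).resolve().parent.parent / "results" / "networks"


def main() -> None:
    ds = build_dataset()
    alns = [ds.alignments[l] for l in NUCLEAR_LOCI + CP_LOCI]
    res = diagnose(alns, ds.taxa, RunConfig(phasing_cap=16))
    OUT.mkdir(parents=True, exist_ok=True)
    cp_id = res.cp_concat.locus_id
    for locus in list(NUCLEAR_LOCI) + [cp_id]:
        net = locus_network(res, locus, ds.taxa, epsilon=0)
        if net is None:
            continue
        short = "cp" if locus == cp_id else locus
        export_network(net, OUT / f"network_{short}.tsv", "tsv")
        export_network(net, OUT / f"network_{short}.dot", "dot")
        node_table(net).to_csv(OUT / f"network_{short}_nodes.tsv",
                               sep="\t", index=False)
        steps = sorted(w for _, _, w in net.edges)
        print(f"{short}: {len(net.nodes)} nodes ({len(net.medians)} medians), "
              f"edge steps {steps}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
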