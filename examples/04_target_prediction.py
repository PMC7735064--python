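"""Seed-match miRNA target prediction over circular and linear transcripts.

Generates sequence pools realising five planted sponge triplets (an exact
8mer site for the partner miRNA embedded in each circRNA body and mRNA
3'UTR, decoys scrubbed of sites), scans them, and applies the top-k /
shared-miRNA ranking rules used by the network stages.
"""

from cernet import synthetic, targets

pools = synthetic.generate_sequences(synthetic.GeneratorConfig(seed=1))
print(f"pools: {len(pools.circ_seqs)} circRNAs, {len(pools.utr_seqs)} 3'UTRs, "
      f"{len(pools.mirna_seqs)} miRNAs")

cm = targets.scan_transcripts(pools.mirna_seqs, pools.circ_seqs, circular=True)
mm = targets.scan_transcripts(pools.mirna_seqs, pools.utr_seqs, circular=False)
print(f"edges with >=1 site: {len(cm)} miRNA-circRNA, {len(mm)} miRNA-mRNA")

e = cm[0]
s = e.sites[0]
print(f"\nexample edge {e.source} -> {e.target}: score {e.score} "
      f"({s.site_class} at [{s.start},{s.end}))")
# score = 5*8mer + 3*7mer-m8 + 2*7mer-A1 + 1*6mer over the edge's sites

per_circ = targets.score_and_rank(cm, top_k=20, group_by="target")
top_lists = {c: [x.source for x in es] for c, es in per_circ.items()}
shared = targets.shared_target_filter(top_lists, min_sources=2)
print(f"\nmiRNAs sponged by >=2 circRNAs: {sorted(shared) or 'none'} "
      "(planted triplets use distinct miRNAs, so sharing only arises by chance)")
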