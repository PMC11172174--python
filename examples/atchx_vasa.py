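"""Cross ping-pong between repeat-cluster piRNAs and vasa alleles.

An X-linked repeat consensus produces piRNAs partially complementary to
the vasa transcripts of the sibling species. The simulated sim-like
allele is 95% identical to the consensus, so cluster piRNAs map onto it
within a 3-mismatch budget and form 10-nt 5'-overlap pairs with
allele-derived piRNAs; the mel-like allele (80% identity) fails the
mapping gate and shows no signature.
"""

from hspirna import alleles
from hspirna.simulate import simulate_atchx_scenario

ax = simulate_atchx_scenario(seed=9)
report = alleles.vasa_atchx_report(
    ax.cluster_reads, ax.allele_reads, ax.alleles, ax.consensus, ax.region_offset
)

for label, entry in report.items():
    score = entry["z10"]
    z = f"{score.z10:.2f}" if score.defined else f"undefined ({score.note})"
    print(
        f"vasa_{label}: identity to consensus {ax.identity[label]:.0%}, "
        f"cluster piRNAs mapped {entry['n_cluster_alignments']}, cross z10 = {z}"
    )
print(
    "\nA defined z10 >= 3 for one allele only indicates allele-specific\n"
    "piRNA targeting - the epigenetic asymmetry between the two vasa copies."
)
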