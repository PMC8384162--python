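"""Turn trained convolution kernels into DNA motifs.

After training, each first-layer kernel is summarised by the position
frequency matrix of its best-activating subsequences over the positive
set, trimmed by information content, converted to a log-odds PWM and
clustered to remove redundancy. Cluster centres are written in MEME
format.
"""

from g4net import (
    ModelSpec,
    SyntheticConfig,
    consensus,
    count_g_stretches,
    extract_motifs,
    generate_dataset,
    motif_similarity,
    planted_motif_pwm,
    train,
    write_motifs,
)

dataset, _ = generate_dataset(SyntheticConfig(n_pos=1000, n_neg=1000, seed=1))
model = train(ModelSpec(n_kernels=64, epochs=15), dataset, seed=1)

positives = [e.sequence for e in dataset.subset("train") if e.label == 1]
result = extract_motifs(model, positives)
print(f"{len(result['pfms'])}/{model.spec.n_kernels} kernels survived "
      f"information-content trimming; {len(result['clusters'])} motif clusters")

reference = planted_motif_pwm(width=model.spec.kernel_size, seed=0)
for cluster in result["clusters"]:
    cons = consensus(cluster.center)
    n_stretch, lengths = count_g_stretches(cons)
    _, ncor, _, _ = motif_similarity(reference, cluster.center)
    print(f"  {cluster.label}: {len(cluster.members):2d} kernels, "
          f"consensus {cons}, {n_stretch} GG+ stretches {lengths}, "
          f"ncor to planted motif {ncor:.2f}")

write_motifs([c.center_pfm for c in result["clusters"]], "cluster_motifs.meme")
print("wrote cluster motifs to cluster_motifs.meme; stretches of >= 2 Gs in "
      "the consensus mirror the G-run structure of the planted canonical G4")
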