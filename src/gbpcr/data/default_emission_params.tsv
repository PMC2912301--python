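# Default genotype-emission parameters P(Y | X^N = x, W = w).
# Columns: x = normal-cell genotype (Het | Hom | ANY for the IBD/UPD row),
# w = aberration class (-3 IBD/UPD, -2 homozygous deletion, -1 loss,
# 0 normal (shared with gain), 2 amplification), then the probabilities of the
# detected call y in {NoCall, Het, NHet}.  Each row sums to 1.
# These defaults encode the qualitative structure of genotype detection on
# SNP arrays for mixed tumor/normal samples: heterozygosity survives a loss
# only rarely (normal-cell contamination), Hom SNPs are essentially never
# called Het, homozygous deletions inflate the NoCall rate, one-allele
# amplification pushes Het calls toward NHet, and IBD/UPD regions behave as
# homozygous runs with ~2% residual Het and a normal-region NoCall rate.
# They are implementation defaults, meant to be replaced by per-platform
# estimates from paired normal/tumor samples when available.
x	w	p_nocall	p_het	p_nhet
Het	-2	0.60	0.03	0.37
Hom	-2	0.60	0.01	0.39
Het	-1	0.04	0.05	0.91
Hom	-1	0.04	0.01	0.95
Het	0	0.02	0.93	0.05
Hom	0	0.02	0.01	0.97
Het	2	0.03	0.45	0.52
Hom	2	0.03	0.01	0.96
ANY	-3	0.02	0.02	0.96
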