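# Minute-scale smoke configuration: same pipeline shape as tiny.yaml at a
# fraction of the cost.  Too short for the loss to cross the 1.0 threshold;
# the analysis stage reports a no-crossing result.
seed: 1
outdir: runs/mini

n_cdr3: 240
n_antigen: 60
n_positive: 30
neg_ratio: 1.0
n_finetune_datasets: 1
rule_kind: shared_kmer
rule_k: 3

corpus_mode: repair_per_epoch
preset: tiny
max_len: 40
dropout: 0.0

pretrain_epochs: 4
pretrain_batch_size: 16
pretrain_lr: 0.003
checkpoint_every: 2
eval_fraction: 0.1

n_splits: 2
finetune_epochs: 2
finetune_batch_size: 16
finetune_lr: 0.001
sweep_stride: 1
include_baseline: true

threshold: 1.0
threshold_series: train
n_sampled_pairs: 40
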