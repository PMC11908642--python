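# Tiny-preset pretraining-dynamics study: repair-per-epoch corpus, shared-kmer
# binding rule, 30 MLM epochs with a checkpoint every 5, 5-split finetuning
# sweep over every checkpoint, loss threshold 1.0 nats on the train series.
seed: 1
outdir: runs/tiny

n_cdr3: 1400
n_antigen: 100
n_positive: 300
neg_ratio: 1.0
n_finetune_datasets: 1
rule_kind: shared_kmer
rule_k: 3

corpus_mode: repair_per_epoch
preset: tiny
max_len: 40
dropout: 0.0

pretrain_epochs: 30
pretrain_batch_size: 16
pretrain_lr: 0.003
checkpoint_every: 5
eval_fraction: 0.1

n_splits: 5
finetune_epochs: 8
finetune_batch_size: 16
finetune_lr: 0.0005
sweep_stride: 1
include_baseline: true

threshold: 1.0
threshold_series: train
n_sampled_pairs: 200
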