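# Frozen full-size classifier configuration.
#
# This layout is pinned by the published parameter totals of the model
# (553,794 total = 549,890 trainable + 3,904 non-trainable batch-norm
# running statistics) and must not be edited casually: tests assert the
# counts exactly.
#
# Batch-norm placement (also part of the frozen reading):
#   - stem: batch norm after the 7x7 conv
#   - identity blocks: batch norm after each conv, and on the 1x1
#     projection inserted when the input channel count differs from F3
#   - convolution blocks: batch norm before each conv (pre-activation);
#     plain 1x1 shortcut without batch norm
#   - inception blocks and head: no batch norm
input: [256, 256, 1]
stem:
  filters: 32
  kernel: 7
  stride: 2
  pool_kernel: 3
  pool_stride: 2
blocks:
  - {kind: inception, filters: [64, 64, 128, 16, 64, 32]}
  - {kind: inception, filters: [32, 64, 96, 16, 32, 32]}
  - {kind: identity, filters: [64, 64, 256]}
  - {kind: identity, filters: [64, 64, 256]}
  - {kind: identity, filters: [64, 64, 256]}
  - {kind: convolution, filters: [32, 32, 64], stride: 1}
  - {kind: convolution, filters: [64, 64, 128], stride: 2}
head:
  pool_kernel: 5
  pool_stride: 3
  conv_filters: 64
  classes: 2
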