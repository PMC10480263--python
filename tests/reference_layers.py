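"""Reference 61-entry layer-kind sequence of the full-scale generator,
written out explicitly as the independent oracle for architecture tests."""

FULL_SCALE_GENERATOR_LAYERS = [
    "Image Input Layer",            # 1
    "Convolution 2D Layer",         # 2
    "Leaky ReLU Layer",             # 3
    "Convolution 2D Layer",         # 4
    "Batch Normalization Layer",    # 5
    "Leaky ReLU Layer",             # 6
    "Convolution 2D Layer",         # 7
    "Batch Normalization Layer",    # 8
    "Leaky ReLU Layer",             # 9
    "Convolution 2D Layer",         # 10
    "Batch Normalization Layer",    # 11
    "Leaky ReLU Layer",             # 12
    "Convolution 2D Layer",         # 13
    "Batch Normalization Layer",    # 14
    "Leaky ReLU Layer",             # 15
    "Convolution 2D Layer",         # 16
    "Batch Normalization Layer",    # 17
    "Leaky ReLU Layer",             # 18
    "Convolution 2D Layer",         # 19
    "Batch Normalization Layer",    # 20
    "Leaky ReLU Layer",             # 21
    "Convolution 2D Layer",         # 22
    "Batch Normalization Layer",    # 23
    "Leaky ReLU Layer",             # 24
    "Transposed Convolution 2D Layer",  # 25
    "Batch Normalization Layer",    # 26
    "Dropout Layer",                # 27
    "Leaky ReLU Layer",             # 28
    "Depth Concatenation Layer",    # 29
    "Transposed Convolution 2D Layer",  # 30
    "Batch Normalization Layer",    # 31
    "Dropout Layer",                # 32
    "Leaky ReLU Layer",             # 33
    "Depth Concatenation Layer",    # 34
    "Transposed Convolution 2D Layer",  # 35
    "Batch Normalization Layer",    # 36
    "Dropout Layer",                # 37
    "Leaky ReLU Layer",             # 38
    "Depth Concatenation Layer",    # 39
    "Transposed Convolution 2D Layer",  # 40
    "Batch Normalization Layer",    # 41
    "Dropout Layer",                # 42
    "Leaky ReLU Layer",             # 43
    "Depth Concatenation Layer",    # 44
    "Transposed Convolution 2D Layer",  # 45
    "Batch Normalization Layer",    # 46
    "Leaky ReLU Layer",             # 47
    "Depth Concatenation Layer",    # 48
    "Transposed Convolution 2D Layer",  # 49
    "Batch Normalization Layer",    # 50
    "Leaky ReLU Layer",             # 51
    "Depth Concatenation Layer",    # 52
    "Transposed Convolution 2D Layer",  # 53
    "Batch Normalization Layer",    # 54
    "Leaky ReLU Layer",             # 55
    "Depth Concatenation Layer",    # 56
    "Transposed Convolution 2D Layer",  # 57
    "Batch Normalization Layer",    # 58
    "Leaky ReLU Layer",             # 59
    "Depth Concatenation Layer",    # 60
    "Convolution 2D Layer",         # 61
]
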