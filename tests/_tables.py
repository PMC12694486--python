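"""Published per-emotion explanation-metric values and multi-seed summary rows
for the two candidate architectures, used as inputs to the aggregation and
confidence-interval routines."""

# per-emotion seven-metric values, three-layer (64,128,256) candidate
XAI_PER_CLASS_3LAYER = {
    "angry": {
        "original_confidence": 0.982, "iauc": 0.226, "dauc": 0.258, "ad": 0.708,
        "ic": 0.436, "ada": 0.713, "active_pixels": 0.401,
        "accuracy_after_masking": 0.287,
    },
    "happy": {
        "original_confidence": 0.992, "iauc": 0.268, "dauc": 0.211, "ad": 0.369,
        "ic": 0.519, "ada": 0.331, "active_pixels": 0.373,
        "accuracy_after_masking": 0.669,
    },
    "sad": {
        "original_confidence": 0.970, "iauc": 0.230, "dauc": 0.263, "ad": 0.690,
        "ic": 0.414, "ada": 0.702, "active_pixels": 0.464,
        "accuracy_after_masking": 0.298,
    },
    "neutral": {
        "original_confidence": 0.962, "iauc": 0.699, "dauc": 0.672, "ad": 0.308,
        "ic": 0.768, "ada": 0.303, "active_pixels": 0.451,
        "accuracy_after_masking": 0.697,
    },
}

# per-emotion seven-metric values, four-layer (64,128,256,512) candidate
XAI_PER_CLASS_4LAYER = {
    "angry": {
        "original_confidence": 0.972, "iauc": 0.191, "dauc": 0.230, "ad": 0.557,
        "ic": 0.222, "ada": 0.563, "active_pixels": 0.481,
        "accuracy_after_masking": 0.437,
    },
    "happy": {
        "original_confidence": 0.965, "iauc": 0.145, "dauc": 0.247, "ad": 0.456,
        "ic": 0.355, "ada": 0.422, "active_pixels": 0.547,
        "accuracy_after_masking": 0.578,
    },
    "sad": {
        "original_confidence": 0.912, "iauc": 0.154, "dauc": 0.197, "ad": 0.667,
        "ic": 0.234, "ada": 0.674, "active_pixels": 0.529,
        "accuracy_after_masking": 0.326,
    },
    "neutral": {
        "original_confidence": 0.918, "iauc": 0.777, "dauc": 0.765, "ad": 0.177,
        "ic": 0.920, "ada": 0.172, "active_pixels": 0.510,
        "accuracy_after_masking": 0.828,
    },
}

# published macro (class-mean) rows for the same two candidates
XAI_MACRO_3LAYER = {
    "original_confidence": 0.976, "iauc": 0.356, "dauc": 0.351, "ad": 0.519,
    "ic": 0.534, "ada": 0.512, "active_pixels": 0.422,
    "accuracy_after_masking": 0.488,
}
XAI_MACRO_4LAYER = {
    "original_confidence": 0.942, "iauc": 0.317, "dauc": 0.360, "ad": 0.464,
    "ic": 0.432, "ada": 0.458, "active_pixels": 0.517,
    "accuracy_after_masking": 0.542,
}

# multi-seed summary rows (percent): metric -> (mean, std, ci_lower, ci_upper),
# computed over 10 seeds
SEED_SUMMARY = {
    "FER2013": {
        "Accuracy": (71.59, 0.37, 71.33, 71.86),
        "F1": (71.52, 0.36, 71.27, 71.78),
        "Recall": (71.59, 0.37, 71.33, 71.86),
        "Precision": (72.30, 0.34, 72.05, 72.55),
    },
    "ExpW": {
        "Accuracy": (68.82, 0.29, 68.61, 69.03),
        "F1": (68.09, 0.25, 67.91, 68.27),
        "Recall": (68.82, 0.29, 68.61, 69.03),
        "Precision": (68.00, 0.33, 67.76, 68.24),
    },
    "RAF-DB": {
        "Accuracy": (81.24, 0.68, 80.75, 81.72),
        "F1": (81.06, 0.69, 80.56, 81.55),
        "Recall": (81.24, 0.68, 80.75, 81.72),
        "Precision": (81.16, 0.76, 80.61, 81.70),
    },
}
N_SEEDS = 10
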