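"""Published worked examples: per-classifier confusion counts and the five
derived percentage metrics (AC, PR, SE, SP, F1S) printed alongside them.

Row layout: (table, row name, TP, FN, TN, FP, AC, PR, SE, SP, F1S).
"""

ROWS = [
    # individual deep features, SoftMax head — FLAIR LGG/HGG
    ("t3", "LGG/HGG VGG16",       139, 10, 138, 13, 92.3333, 91.4474, 93.2886, 91.3907, 92.3588),
    ("t3", "LGG/HGG DenseNet101", 135, 14, 140, 11, 91.6667, 92.4658, 90.6040, 92.7152, 91.5254),
    ("t3", "LGG/HGG ResNet101",   136, 13, 134, 17, 90.0000, 88.8889, 91.2752, 88.7417, 90.0662),
    ("t3", "LGG/HGG VGG19",       133, 19, 136, 12, 89.6667, 91.7241, 87.5000, 91.8919, 89.5623),
    ("t3", "LGG/HGG ResNet50",    133, 17, 135, 15, 89.3333, 89.8649, 88.6667, 90.0000, 89.2617),
    ("t3", "LGG/GBM VGG16",       138, 14, 138, 10, 92.0000, 93.2432, 90.7895, 93.2432, 92.0000),
    ("t3", "LGG/GBM DenseNet101", 136, 13, 138, 13, 91.3333, 91.2752, 91.2752, 91.3907, 91.2752),
    ("t3", "LGG/GBM VGG19",       134, 19, 136, 11, 90.0000, 92.4138, 87.5817, 92.5170, 89.9329),
    ("t3", "LGG/GBM ResNet101",   131, 18, 137, 14, 89.3333, 90.3448, 87.9195, 90.7285, 89.1156),
    ("t3", "LGG/GBM ResNet50",    132, 17, 135, 16, 89.0000, 89.1892, 88.5906, 89.4040, 88.8889),
    # FLAIR modality — dual-deep and DL+ML fusions
    ("t4", "DualDeep SoftMax", 143, 5, 146, 6, 96.3333, 95.9732, 96.6216, 96.0526, 96.2963),
    ("t4", "DualDeep DT",      146, 6, 145, 3, 97.0000, 97.9866, 96.0526, 97.9730, 97.0100),
    ("t4", "DualDeep RF",      144, 7, 145, 4, 96.3333, 97.2973, 95.3642, 97.3154, 96.3211),
    ("t4", "DualDeep KNN",     145, 4, 144, 7, 96.3333, 95.3947, 97.3154, 95.3642, 96.3455),
    ("t4", "DualDeep SVM",     144, 7, 146, 3, 96.6667, 97.9592, 95.3642, 97.9866, 96.6443),
    ("t4", "DL+ML SoftMax",    146, 2, 148, 4, 98.0000, 97.3333, 98.6486, 97.3684, 97.9866),
    ("t4", "DL+ML DT",         148, 3, 144, 5, 97.3333, 96.7320, 98.0132, 96.6443, 97.3684),
    ("t4", "DL+ML RF",         150, 1, 147, 2, 99.0000, 98.6842, 99.3377, 98.6577, 99.0099),
    ("t4", "DL+ML KNN",        151, 1, 147, 1, 99.3333, 99.3421, 99.3421, 99.3243, 99.3421),
    ("t4", "DL+ML SVM",        147, 4, 148, 1, 98.3333, 99.3243, 97.3510, 99.3289, 98.3278),
    # T2 modality — dual-deep and DL+ML fusions
    ("t5", "DualDeep SoftMax", 142, 6, 145, 7, 95.6667, 95.3020, 95.9459, 95.3947, 95.6229),
    ("t5", "DualDeep DT",      144, 6, 145, 5, 96.3333, 96.6443, 96.0000, 96.6667, 96.3211),
    ("t5", "DualDeep RF",      143, 9, 146, 2, 96.3333, 98.6207, 94.0789, 98.6486, 96.2963),
    ("t5", "DualDeep KNN",     145, 2, 144, 9, 96.3333, 94.1558, 98.6395, 94.1176, 96.3455),
    ("t5", "DualDeep SVM",     144, 7, 146, 3, 96.6667, 97.9592, 95.3642, 97.9866, 96.6443),
    ("t5", "DL+ML SoftMax",    146, 5, 147, 2, 97.6667, 98.6486, 96.6887, 98.6577, 97.6589),
    ("t5", "DL+ML DT",         146, 1, 150, 3, 98.6667, 97.9866, 99.3197, 98.0392, 98.6486),
    ("t5", "DL+ML RF",         146, 3, 148, 3, 98.0000, 97.9866, 97.9866, 98.0132, 97.9866),
    ("t5", "DL+ML KNN",        147, 2, 149, 2, 98.6667, 98.6577, 98.6577, 98.6755, 98.6577),
    ("t5", "DL+ML SVM",        152, 1, 147, 0, 99.6667, 100.0000, 99.3464, 100.0000, 99.6721),
]
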