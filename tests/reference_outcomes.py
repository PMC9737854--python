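"""Published per-subject PLUS model outcomes of the reference cohort.

Two occupational groups (20 physiotherapists, 20 IT professionals), each
evaluated at three timepoints: before the COVID-19 pandemic (t1), during
its second year (t2) and during the war in the neighboring country (t3).
The raw questionnaire answers behind these outcomes were never published;
the printed composite scores (3 decimal places) and their printed summary
rows are used to pin down the summary-statistic conventions.
"""

# columns: (group, timepoint) -> 20 per-subject PLUS scores
OUTCOMES = {
    ("group1", "t1"): [
        0.297, 0.428, 0.445, 0.426, 0.324, 0.391, 0.482, 0.361, 0.500, 0.391,
        0.406, 0.445, 0.445, 0.445, 0.324, 0.468, 0.445, 0.352, 0.406, 0.445,
    ],
    ("group1", "t2"): [
        0.236, 0.339, 0.406, 0.395, 0.315, 0.391, 0.445, 0.286, 0.406, 0.376,
        0.350, 0.322, 0.406, 0.253, 0.315, 0.445, 0.293, 0.338, 0.297, 0.400,
    ],
    ("group1", "t3"): [
        0.222, 0.244, 0.191, 0.361, 0.182, 0.241, 0.278, 0.210, 0.247, 0.206,
        0.217, 0.200, 0.297, 0.213, 0.188, 0.322, 0.221, 0.291, 0.195, 0.235,
    ],
    ("group2", "t1"): [
        0.500, 0.500, 0.500, 0.500, 0.500, 0.500, 0.500, 0.500, 0.462, 0.500,
        0.462, 0.500, 0.500, 0.594, 0.500, 0.500, 0.500, 0.500, 0.500, 0.500,
    ],
    ("group2", "t2"): [
        0.500, 0.500, 0.500, 0.428, 0.462, 0.361, 0.500, 0.500, 0.406, 0.380,
        0.428, 0.406, 0.428, 0.594, 0.462, 0.477, 0.428, 0.462, 0.428, 0.500,
    ],
    ("group2", "t3"): [
        0.500, 0.500, 0.500, 0.462, 0.500, 0.428, 0.500, 0.500, 0.500, 0.462,
        0.500, 0.462, 0.462, 0.555, 0.500, 0.500, 0.500, 0.500, 0.500, 0.500,
    ],
}

# published summary rows per column, at the precision they were printed
SUMMARIES = {
    ("group1", "t1"): dict(sum=8.223, min=0.297, q1=0.383, median=0.428,
                           q3=0.445, max=0.500, mean=0.411, sd=0.056),
    ("group1", "t2"): dict(sum=7.014, min=0.236, q1=0.311, median=0.350,
                           q3=0.401, max=0.445, mean=0.351, sd=0.061),
    ("group1", "t3"): dict(sum=4.761, min=0.182, q1=0.204, median=0.222,
                           q3=0.255, max=0.361, mean=0.238, sd=0.049),
    ("group2", "t1"): dict(sum=10.017, min=0.462, q1=0.500, median=0.500,
                           q3=0.500, max=0.594, mean=0.501, sd=0.025),
    ("group2", "t2"): dict(sum=9.149, min=0.361, q1=0.428, median=0.462,
                           q3=0.500, max=0.594, mean=0.457, sd=0.054),
    ("group2", "t3"): dict(sum=9.831, min=0.428, q1=0.491, median=0.500,
                           q3=0.500, max=0.555, mean=0.492, sd=0.026),
}
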