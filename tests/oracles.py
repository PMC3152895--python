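"""Independent brute-force reference implementations.

Everything here works on plain Python ints/floats with explicit loops and
is deliberately written without reusing any package code, so the fast
vectorized implementations can be checked against a second route.
"""

import math


def brute_com_features(pixels, ng):
    """Eleven co-occurrence statistics by explicit enumeration.

    ``pixels``: list of lists of grey levels in 1..ng.
    """
    counts = {}
    rows = len(pixels)
    cols = len(pixels[0])
    for x in range(rows):
        for y in range(cols - 1):
            i, j = pixels[x][y], pixels[x][y + 1]
            counts[(i, j)] = counts.get((i, j), 0) + 1
            counts[(j, i)] = counts.get((j, i), 0) + 1
    total = sum(counts.values())
    p = {key: value / total for key, value in counts.items()}

    px = {}
    for (i, j), prob in p.items():
        px[i] = px.get(i, 0.0) + prob
    mu = sum(i * prob for i, prob in px.items())
    var = sum((i - mu) ** 2 * prob for i, prob in px.items())

    p_sum = {}
    p_diff = {}
    for (i, j), prob in p.items():
        p_sum[i + j] = p_sum.get(i + j, 0.0) + prob
        p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + prob

    asm = sum(prob**2 for prob in p.values())
    contrast = sum(n**2 * prob for n, prob in p_diff.items())
    if var > 0:
        correlation = (
            sum(i * j * prob for (i, j), prob in p.items()) - mu * mu
        ) / var
    else:
        correlation = 0.0
    entropy = -sum(prob * math.log(prob) for prob in p.values() if prob > 0)
    sum_of_squares = sum((i - mu) ** 2 * prob for (i, j), prob in p.items())
    idm = sum(prob / (1 + (i - j) ** 2) for (i, j), prob in p.items())
    sum_average = sum(k * prob for k, prob in p_sum.items())
    sum_variance = sum((k - sum_average) ** 2 * prob for k, prob in p_sum.items())
    sum_entropy = -sum(prob * math.log(prob) for prob in p_sum.values() if prob > 0)
    mu_d = sum(n * prob for n, prob in p_diff.items())
    difference_variance = sum((n - mu_d) ** 2 * prob for n, prob in p_diff.items())
    difference_entropy = -sum(
        prob * math.log(prob) for prob in p_diff.values() if prob > 0
    )
    return {
        "Angular Second Moment": asm,
        "Contrast": contrast,
        "Correlation": correlation,
        "Entropy": entropy,
        "Sum of Squares": sum_of_squares,
        "Inverse Difference Moment": idm,
        "Sum Average": sum_average,
        "Sum Variance": sum_variance,
        "Sum Entropy": sum_entropy,
        "Difference Variance": difference_variance,
        "Difference Entropy": difference_entropy,
    }


def brute_rlm_lines(pixels, theta):
    """All scan lines of a direction as lists of grey levels."""
    rows = len(pixels)
    cols = len(pixels[0])
    lines = []
    if theta == 0:
        for x in range(rows):
            lines.append([pixels[x][y] for y in range(cols)])
    elif theta == 90:
        for y in range(cols):
            lines.append([pixels[x][y] for x in range(rows)])
    elif theta == 45:
        # up-right diagonals: start from every cell of the left column and
        # the bottom row, stepping (-1, +1)
        starts = [(x, 0) for x in range(rows)] + [(rows - 1, y) for y in range(1, cols)]
        for x0, y0 in starts:
            line = []
            x, y = x0, y0
            while x >= 0 and y < cols:
                line.append(pixels[x][y])
                x -= 1
                y += 1
            lines.append(line)
    elif theta == 135:
        # down-right diagonals: start from every cell of the top row and the
        # left column, stepping (+1, +1)
        starts = [(0, y) for y in range(cols)] + [(x, 0) for x in range(1, rows)]
        for x0, y0 in starts:
            line = []
            x, y = x0, y0
            while x < rows and y < cols:
                line.append(pixels[x][y])
                x += 1
                y += 1
            lines.append(line)
    else:
        raise ValueError(theta)
    return lines


def brute_runs(pixels, theta):
    """All maximal runs of a direction as (grey level, length) pairs."""
    runs = []
    for line in brute_rlm_lines(pixels, theta):
        k = 0
        while k < len(line):
            length = 1
            while k + length < len(line) and line[k + length] == line[k]:
                length += 1
            runs.append((line[k], length))
            k += length
    return runs


def brute_rlm_features(pixels, theta):
    """The five run-length statistics computed from the raw run list."""
    runs = brute_runs(pixels, theta)
    n_runs = len(runs)
    n_pixels = len(pixels) * len(pixels[0])
    sre = sum(1.0 / length**2 for _, length in runs) / n_runs
    lre = sum(float(length**2) for _, length in runs) / n_runs
    per_level = {}
    per_length = {}
    for level, length in runs:
        per_level[level] = per_level.get(level, 0) + 1
        per_length[length] = per_length.get(length, 0) + 1
    gln = sum(count**2 for count in per_level.values()) / n_runs
    rln = sum(count**2 for count in per_length.values()) / n_runs
    fraction = n_runs / n_pixels
    return {
        "Short Run Emphasis": sre,
        "Long Run Emphasis": lre,
        "Greylevel Non-uniformity": gln,
        "Run Length Non-uniformity": rln,
        "Fraction": fraction,
    }
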