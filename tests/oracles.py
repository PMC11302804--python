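"""Independent reference implementations used as test oracles."""

import numpy as np


def bilinear_upsample_oracle(dose, valid, k):
    """Manual bilinear upsample with NaN propagation, written directly from
    the interpolation formula (independent of scipy.ndimage)."""
    work = np.where(valid, dose, np.nan)
    h, w = dose.shape
    fh, fw = (h - 1) * k + 1, (w - 1) * k + 1
    out = np.empty((fh, fw))
    for i in range(fh):
        y = i / k
        i0 = min(int(np.floor(y)), h - 2)
        fy = y - i0
        for j in range(fw):
            x = j / k
            j0 = min(int(np.floor(x)), w - 2)
            fx = x - j0
            out[i, j] = (
                (1 - fy) * (1 - fx) * work[i0, j0]
                + (1 - fy) * fx * work[i0, j0 + 1]
                + fy * (1 - fx) * work[i0 + 1, j0]
                + fy * fx * work[i0 + 1, j0 + 1]
            )
    # same node convention as production: exact pixel values at coarse nodes
    out[::k, ::k] = work
    return out


def gamma_brute_force(ref_dose, ref_valid, eval_dose, eval_valid,
                      spacing, dta, dose_tols, search_radius_factor=3.0,
                      upsample=3):
    """Exhaustive gamma minimisation over every candidate in the search disc.

    Enumerates the complete candidate set with no early termination, using
    the manual bilinear upsample above and per-offset fancy indexing (a
    different evaluation path from the production sweep). Returns one gamma
    array per dose tolerance.
    """
    k = upsample
    sf = spacing / k
    radius = search_radius_factor * dta
    pad = int(np.ceil(radius / sf))
    fine = bilinear_upsample_oracle(eval_dose, eval_valid, k)
    fine_p = np.pad(fine, pad, constant_values=np.nan)
    h, w = ref_dose.shape
    ii, jj = np.mgrid[0:h, 0:w]
    ref = np.where(ref_valid, ref_dose, np.nan)
    best = [np.full((h, w), np.inf) for _ in dose_tols]
    span = np.arange(-pad, pad + 1)
    for oi in span:
        for oj in span:
            dist = sf * np.hypot(oi, oj)
            if dist > radius + 1e-12:
                continue
            vals = fine_p[pad + k * ii + oi, pad + k * jj + oj]
            delta = vals - ref
            d2 = (dist / dta) ** 2
            for t, tol in enumerate(dose_tols):
                cand = d2 + (delta / tol) ** 2
                ok = np.isfinite(cand)
                best[t][ok] = np.minimum(best[t][ok], cand[ok])
    out = []
    for b in best:
        g = np.sqrt(b)
        g[~np.isfinite(g)] = np.nan
        g[~ref_valid] = np.nan
        out.append(g)
    return out


def reference_wiener(img, size=5):
    """Loop-based adaptive local mean/variance filter (edge-replicated)."""
    k = size // 2
    padded = np.pad(img, k, mode="edge")
    h, w = img.shape
    l_mean = np.empty_like(img, dtype=float)
    l_var = np.empty_like(img, dtype=float)
    for i in range(h):
        for j in range(w):
            win = padded[i:i + size, j:j + size]
            l_mean[i, j] = win.mean()
            l_var[i, j] = win.var()
    noise = l_var.mean()
    return np.where(
        l_var > noise,
        l_mean + (img - l_mean) * (1 - noise / l_var),
        l_mean,
    )


def reference_median(img, size=5):
    """Loop-based median filter (edge-replicated windows)."""
    k = size // 2
    padded = np.pad(img, k, mode="edge")
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.median(padded[i:i + size, j:j + size])
    return out
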