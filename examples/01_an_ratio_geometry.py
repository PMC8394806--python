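"""Measure the Fujioka A/N ratio from four annotated landmarks.

Builds a landmark set in pixel coordinates, computes the adenoid depth A
(perpendicular distance of A' to the Ba-Ar skull-base line), the
nasopharyngeal span N (distance from PNS to the foot of that perpendicular)
and classifies adenoid hypertrophy at the 0.6 ratio threshold.
"""

from adenoceph import LandmarkSet, Point2D, compute_an

landmarks = LandmarkSet(
    Ba=Point2D(100, 200),      # basion: lower end of the skull-base line
    Ar=Point2D(100, 100),      # articulare: upper end of the skull-base line
    Aprime=Point2D(130, 150),  # maximal convexity of the adenoid shadow
    PNS=Point2D(140, 190),     # posterior nasal spine
)

m = compute_an(landmarks)
print(f"A  (adenoid depth)        : {m.A:.3f} px")
print(f"N  (nasopharyngeal span)  : {m.N:.3f} px")
print(f"A/N ratio                 : {m.ratio:.5f}")
print(f"assessment                : {m.label}")
# A/N = 0.530 here: below the 0.6 threshold, so the airway is read as normal.
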