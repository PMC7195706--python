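"""Extended-system arithmetic: rates and mean object sizes from pixel counts.

A segmentation-capable extension would count pixels per class in addition
to objects.  Given those counts, the summary derives the germination rate
(germinated / total seeds), the haustoria development rate (haustoria /
germinated), and the mean physical size of each object class.
"""

from strigacount import segmentation_summary

summary = segmentation_summary(
    n_seeds=6,
    n_germinated=3,
    n_haustoria=2,
    class_pixel_counts={"seed": 400, "radicle": 300, "haustorium": 100},
    pixel_area=0.1,   # mm^2 per pixel, from the camera calibration
)

for key, value in summary.report().items():
    print(f"{key:26} {value}")
# germination_rate 0.5: 3 of 6 seeds germinated; haustoria_rate 0.67:
# 2 of the 3 germinated seeds developed a haustorium; mean sizes are
# class pixels / class objects * pixel_area, in mm^2 per object
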