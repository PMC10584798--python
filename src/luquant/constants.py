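"""Physical constants and default acquisition settings for Lu-177 SPECT.

All lengths are millimetres, activities MBq, times seconds unless a
name says otherwise.
"""

#: Physical half-life of Lu-177 in days (standard evaluated value).
HALF_LIFE_LU177_DAYS = 6.6475
#: Physical half-life of Lu-177 in seconds.
HALF_LIFE_LU177_S = HALF_LIFE_LU177_DAYS * 86400.0

#: Linear attenuation coefficient of water at 208 keV [1/mm] (NIST).
MU_WATER_208KEV = 0.0136

#: Intrinsic detector pixel pitch of the CZT modules [mm]; also the
#: default reconstruction voxel size.
CZT_PIXEL_MM = 2.46

#: Photopeak window: 208 keV +/- 6 %.
PHOTOPEAK_CENTER_KEV = 208.0
PHOTOPEAK_FRACTION = 0.06
#: Scatter window: 185 keV +/- 5 %.
SCATTER_CENTER_KEV = 185.0
SCATTER_FRACTION = 0.05

#: Default dual-energy-window scaling constant k.  The photopeak
#: contamination from down-scattered and tailing photons on a CZT
#: detector is only partially mirrored by the adjacent window, so k is
#: a system-specific calibration well below the classic 0.5 used for
#: NaI Compton windows.
DEW_K = 0.1

#: Default relative uncertainty of the activity measured in the
#: radionuclide calibrator.
ACTIVITY_REL_UNCERTAINTY = 0.02
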