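library_id	sample_code	replicate	series
SD.g1.r1	SD.g1	1	germination
SD.g1.r2	SD.g1	2	germination
SD.g2.r1	SD.g2	1	germination
SD.g2.r2	SD.g2	2	germination
SD.g3.r1	SD.g3	1	germination
SD.g3.r2	SD.g3	2	germination
M1.r1	M1	1	meristem
M1.r2	M1	2	meristem
M2.r1	M2	1	meristem
M2.r2	M2	2	meristem
M3.r1	M3	1	meristem
M3.r2	M3	2	meristem
M4.r1	M4	1	meristem
M4.r2	M4	2	meristem
M5.r1	M5	1	meristem
M5.r2	M5	2	meristem
M6.r1	M6	1	meristem
M6.r2	M6	2	meristem
M7.r1	M7	1	meristem
M7.r2	M7	2	meristem
M8.r1	M8	1	meristem
M8.r2	M8	2	meristem
M9.r1	M9	1	meristem
M9.r2	M9	2	meristem
M10.r1	M10	1	meristem
M10.r2	M10	2	meristem
F1.r1	F1	1	flower
F1.r2	F1	2	flower
F2.r1	F2	1	flower
F2.r2	F2	2	flower
F3.r1	F3	1	flower
F3.r2	F3	2	flower
F4.r1	F4	1	flower
F4.r2	F4	2	flower
F5.r1	F5	1	flower
F5.r2	F5	2	flower
F6.r1	F6	1	flower
F6.r2	F6	2	flower
F7.r1	F7	1	flower
F7.r2	F7	2	flower
F8.r1	F8	1	flower
F8.r2	F8	2	flower
F9.r1	F9	1	flower
F9.r2	F9	2	flower
F10.r1	F10	1	flower
F10.r2	F10	2	flower
F11.r1	F11	1	flower
F11.r2	F11	2	flower
F12.r1	F12	1	flower
F12.r2	F12	2	flower
F13.r1	F13	1	flower
F13.r2	F13	2	flower
F14.r1	F14	1	flower
F14.r2	F14	2	flower
F15.r1	F15	1	flower
F15.r2	F15	2	flower
F16.r1	F16	1	flower
F16.r2	F16	2	flower
F17.r1	F17	1	flower
F17.r2	F17	2	flower
F18.r1	F18	1	flower
F18.r2	F18	2	flower
F19.r1	F19	1	flower
F19.r2	F19	2	flower
S.H.r1	S.H	1	seedling_parts
S.H.r2	S.H	2	seedling_parts
S.C.r1	S.C	1	seedling_parts
S.C.r2	S.C	2	seedling_parts
S.M.r1	S.M	1	seedling_parts
S.M.r2	S.M	2	seedling_parts
F.AN.r1	F.AN	1	other
F.AN.r2	F.AN	2	other
F.AN.ad.r1	F.AN.ad	1	other
F.AN.ad.r2	F.AN.ad	2	other
F.AN.y.r1	F.AN.y	1	other
F.AN.y.r2	F.AN.y	2	other
F.PT.ad.r1	F.PT.ad	1	other
F.PT.ad.r2	F.PT.ad	2	other
F.SP.ad.r1	F.SP.ad	1	other
F.SP.ad.r2	F.SP.ad	2	other
SD.d.r1	SD.d	1	other
SD.d.r2	SD.d	2	other
SD.y1.r1	SD.y1	1	other
SD.y1.r2	SD.y1	2	other
SD.y2.r1	SD.y2	1	other
SD.y2.r2	SD.y2	2	other
SD.y5.r1	SD.y5	1	other
SD.y5.r2	SD.y5	2	other
SD1.r1	SD1	1	other
SD1.r2	SD1	2	other
SD2.r1	SD2	1	other
SD2.r2	SD2	2	other
SD3.r1	SD3	1	other
SD3.r2	SD3	2	other
SD4.r1	SD4	1	other
SD4.r2	SD4	2	other
SD5.r1	SD5	1	other
SD5.r2	SD5	2	other
SD6.r1	SD6	1	other
SD6.r2	SD6	2	other
SD7.r1	SD7	1	other
SD7.r2	SD7	2	other
SL1.r1	SL1	1	other
SL1.r2	SL1	2	other
SL2.r1	SL2	1	other
SL2.r2	SL2	2	other
SL3.r1	SL3	1	other
SL3.r2	SL3	2	other
SL4.r1	SL4	1	other
SL4.r2	SL4	2	other
SL5.r1	SL5	1	other
SL5.r2	SL5	2	other
SL6.r1	SL6	1	other
SL6.r2	SL6	2	other
SL.sn2.r1	SL.sn2	1	other
SL.sn2.r2	SL.sn2	2	other
POD.r1	POD	1	other
POD.r2	POD	2	other
POD.sn1.r1	POD.sn1	1	other
POD.sn1.r2	POD.sn1	2	other
POD.y6-7.r1	POD.y6-7	1	other
POD.y6-7.r2	POD.y6-7	2	other
IN.y.r1	IN.y	1	other
IN.y.r2	IN.y	2	other
IN.lg.r1	IN.lg	1	other
IN.lg.r2	IN.lg	2	other
IN.sn.r1	IN.sn	1	other
IN.sn.r2	IN.sn	2	other
L.y.r1	L.y	1	other
L.y.r2	L.y	2	other
L.lg.r1	L.lg	1	other
L.lg.r2	L.lg	2	other
L.sn.r1	L.sn	1	other
L.sn.r2	L.sn	2	other
L.PET.y.r1	L.PET.y	1	other
L.PET.y.r2	L.PET.y	2	other
L.PET.lg.r1	L.PET.lg	1	other
L.PET.lg.r2	L.PET.lg	2	other
L.PET.sn.r1	L.PET.sn	1	other
L.PET.sn.r2	L.PET.sn	2	other
L.VN.lg.r1	L.VN.lg	1	other
L.VN.lg.r2	L.VN.lg	2	other
L.LAM.lg.r1	L.LAM.lg	1	other
L.LAM.lg.r2	L.LAM.lg	2	other
PED.r1	PED	1	other
PED.r2	PED	2	other
AX.r1	AX	1	other
AX.r2	AX	2	other
R.TIP.r1	R.TIP	1	other
R.TIP.r2	R.TIP	2	other
R.EZ.r1	R.EZ	1	other
R.EZ.r2	R.EZ	2	other
R.MZ.r1	R.MZ	1	other
R.MZ.r2	R.MZ	2	other
F.CR.r1	F.CR	1	other
F.CR.r2	F.CR	2	other
F.OV.r1	F.OV	1	other
F.OV.r2	F.OV	2	other
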