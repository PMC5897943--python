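study_id,dataset,clinical_response,predicted_response,score,PDL1,TGFB1,IDO1,IL6,VEGFA,TDO2,PGE2,IL10,LGALS9,FASLG,CD47,CTLA4,PDCD1LG2,GM3,GD2,DC_index
VCMG7N,discovery,non_responder,non_responder,MATCH,25.73,4.14,5.27,14.79,11.31,0.98,4.67,14.50,0.20,-5.99,3.20,10.76,1.36,25.57,25.57,17.85
L11LVL,discovery,non_responder,non_responder,MATCH,18.95,-1.08,-2.33,7.89,14.14,1.38,-7.60,8.51,-0.03,-2.32,3.74,6.15,1.51,14.48,14.48,14.73
UC2LIA,discovery,non_responder,non_responder,MATCH,78.62,44.67,5.44,131.81,48.07,3.35,16.14,41.95,2.68,-2.61,6.30,12.10,2.82,25.52,25.52,40.42
X0152B,discovery,non_responder,non_responder,MATCH,21.87,9.51,0.84,16.17,15.78,0.23,38.50,13.54,-0.43,-7.37,7.44,12.07,1.40,-0.01,-0.01,26.80
QIA43T,discovery,non_responder,non_responder,MATCH,41.42,57.12,-3.64,55.10,40.89,4.06,12.60,36.51,1.78,1.26,1.09,6.57,4.83,21.57,21.57,42.21
J0T9TJ,discovery,non_responder,non_responder,MATCH,44.40,26.90,-2.55,20.21,17.96,1.44,20.71,12.71,5.92,-0.96,2.03,2.24,14.55,14.55,2.56,16.71
3DJF3O,discovery,non_responder,non_responder,MATCH,21.81,7.76,4.19,21.26,9.45,0.78,1.97,11.54,1.58,-8.74,3.34,1.97,1.72,18.63,18.63,18.29
MG6XF2,discovery,non_responder,non_responder,MATCH,11.08,7.54,1.97,81.93,25.47,-0.98,4.74,9.51,1.11,-1.15,2.01,17.50,0.86,5.92,5.92,5.31
C9TGAJ,discovery,responder,responder,MATCH,43.42,23.05,4.64,37.16,31.76,2.75,9.86,25.25,5.24,-11.30,6.60,11.83,4.15,40.30,40.30,37.91
RDD2UW,discovery,responder,responder,MATCH,54.86,49.36,10.35,47.04,22.34,1.97,19.41,22.51,14.47,-0.25,3.40,2.96,4.87,29.93,29.93,32.66
L8MTGU,discovery,responder,responder,MATCH,34.59,18.21,6.31,38.22,16.49,1.36,2.37,17.06,3.48,-8.50,4.08,7.70,2.37,26.69,26.69,23.76
2FCOH7,discovery,responder,non_responder,MISMATCH,31.78,35.02,-7.84,28.65,63.79,4.39,-32.22,23.15,8.79,-5.90,6.16,48.00,8.42,41.16,41.16,26.35
P90A0O,discovery,responder,responder,MATCH,34.09,19.79,5.98,35.86,15.08,1.67,2.38,17.45,6.00,-7.27,4.36,3.32,2.64,29.91,29.91,28.49
195P5D,validation,non_responder,non_responder,MATCH,27.60,15.20,0.97,26.76,12.90,1.33,9.08,16.51,3.54,-8.83,5.99,1.66,45.78,25.94,25.94,26.60
ZNT6MQ,validation,non_responder,non_responder,MATCH,76.54,31.90,-0.45,101.96,36.03,5.64,23.13,40.46,3.63,-0.76,9.05,2.29,10.64,41.99,41.99,48.94
ZX7V33,validation,non_responder,non_responder,MATCH,33.70,5.06,5.19,19.67,6.96,0.71,-0.39,9.31,2.49,-7.64,3.26,1.76,1.45,14.28,14.28,16.00
F3FK2W,validation,non_responder,responder,MISMATCH,63.86,17.70,3.87,25.27,15.83,-3.05,5.47,19.72,-4.96,-4.56,8.16,7.10,2.98,24.03,24.03,34.14
6QFSVV,validation,non_responder,responder,MISMATCH,43.31,44.18,5.31,42.83,19.40,1.86,14.62,18.65,12.46,-0.10,1.88,2.10,3.29,26.70,26.70,25.50
IPUAS9,validation,non_responder,non_responder,MATCH,28.49,10.25,5.43,25.29,10.86,2.11,4.85,11.77,2.65,-1.00,3.44,7.14,1.51,13.54,13.54,15.01
GI7AGZ,validation,non_responder,responder,MISMATCH,142.53,96.10,8.52,114.25,69.40,4.12,39.61,49.30,25.56,0.38,5.44,12.89,12.02,67.05,67.05,64.92
CZH5YD,validation,non_responder,non_responder,MATCH,76.21,17.60,8.11,96.00,30.61,3.17,7.75,28.32,9.96,-2.31,5.56,7.63,32.48,32.48,3.75,26.89
67K46M,validation,non_responder,non_responder,MATCH,-8.33,3.34,-1.51,8.23,2.40,-0.63,2.74,2.07,-0.55,-6.25,175.23,-0.45,0.83,3.79,3.79,4.20
3HDJMG,validation,non_responder,non_responder,MATCH,4.42,4.70,1.12,17.12,9.89,1.35,0.08,10.07,0.06,-1.35,4.61,7.45,0.17,14.17,14.17,14.40
26YMUF,validation,responder,responder,MATCH,29.26,9.43,5.84,24.75,10.64,2.47,5.95,13.47,2.17,-1.63,6.50,7.43,0.67,25.92,25.92,23.23
MJXYP6,validation,responder,responder,MATCH,137.90,43.67,190.94,91.44,102.75,16.56,49.41,79.19,6.75,2.07,7.67,144.61,4.60,4.13,4.13,73.86
M9GYO4,validation,responder,responder,MATCH,185.53,12.45,5.87,53.86,33.00,4.15,11.69,25.87,2.67,-3.16,9.09,21.21,2.04,36.09,36.09,31.90
L6ADEL,validation,responder,responder,MATCH,37.43,14.64,4.80,31.24,18.91,1.69,-1.21,20.73,3.77,-13.77,6.07,5.03,4.41,40.54,40.54,34.94
DFZLO2,validation,responder,responder,MATCH,60.53,122.62,-0.26,51.22,57.41,3.61,229.90,62.31,8.86,-6.31,11.09,16.77,38.08,38.08,8.48,79.85
SA97V5,validation,responder,responder,MATCH,67.03,12.87,15.30,56.46,21.85,-0.43,20.30,20.85,1.21,-1.90,5.28,10.32,2.79,20.96,20.96,23.81
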