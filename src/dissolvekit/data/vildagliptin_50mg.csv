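product,time_min,mean,sd,n
Ref,10,98.53,0.9,3
Ref,15,98.57,0.94,3
Ref,20,98.00,0.94,3
Ref,30,97.10,0.91,3
Ref,45,96.05,0.97,3
V-1,10,98.34,3.5,3
V-1,15,100.01,0.74,3
V-1,20,99.13,0.79,3
V-1,30,98.48,0.80,3
V-1,45,97.45,0.89,3
V-2,10,98.48,2.2,3
V-2,15,103.41,1.33,3
V-2,20,102.67,1.53,3
V-2,30,101.86,1.52,3
V-2,45,100.97,1.55,3
V-3,10,96.78,2.5,3
V-3,15,99.44,1.09,3
V-3,20,98.29,1.02,3
V-3,30,97.16,1.05,3
V-3,45,96.40,1.03,3
V-4,10,98.17,0.69,3
V-4,15,97.77,0.66,3
V-4,20,96.48,0.64,3
V-4,30,95.80,0.76,3
V-4,45,94.92,0.64,3
V-5,10,97.50,1.48,3
V-5,15,97.27,1.41,3
V-5,20,96.10,1.42,3
V-5,30,95.09,1.49,3
V-5,45,93.97,1.46,3
V-6,10,99.26,1.13,3
V-6,15,98.93,0.77,3
V-6,20,97.76,0.86,3
V-6,30,96.91,0.78,3
V-6,45,95.96,0.87,3
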