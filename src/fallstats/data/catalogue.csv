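name,year,positions,sensors,sampling_rate_hz,sampling_rate_spread_hz,accel_range_g,n_samples_total,n_adl,n_fall,n_subjects,age_min,age_max,weight_min,weight_max,height_min,height_max,release_group,notes
DLR,2010,waist,accelerometer;gyroscope;magnetometer,100,,5,1017,961,56,19,23,52,,,160,183,,belt-mounted external IMU
LDPA,2010,ankle;waist;chest,,10,,,175,100,75,5,,,,,,,,localization tags (x;y;z position); no inertial sensor
MobiFall,2013,thigh,accelerometer;gyroscope;orientation,87,,2,630,342,288,24,22,47,50,103,160,189,,smartphone in trouser pocket
MobiAct,2016,thigh,accelerometer;gyroscope;orientation,87,,2,2526,1879,647,57,20,47,,,,,,smartphone in trouser pocket
EvAAL,2013,chest;thigh,accelerometer,50,,16,57,55,2,1,,,50,120,160,193,,two external IMUs
TST,2014,waist;wrist,accelerometer,100,,8,264,132,132,11,22,39,,,162,197,,also Kinect depth data (out of scope)
tFall,2014,thigh,accelerometer,45,12,2,10909,9883,1026,10,20,42,54,98,161,184,,smartphone in pocket or handbag; ADLs from daily-life monitoring
UR,2014,waist,accelerometer,256,,8,70,40,30,6,,,,,,,,ages over 26; also camera data (out of scope)
Erciyes,2014,chest;head;ankle;thigh;wrist;waist,accelerometer;gyroscope;magnetometer,25,,16,3302,1476,1826,17,19,27,47,92,157,184,,six external IMUs
CogentLabs,2015,chest;thigh,accelerometer;gyroscope,100,,8,1968,1520,448,42,18,51,43,108,150,187,,
GravityProject,2015,thigh;wrist,accelerometer,50,,16,117,45,72,2,26,32,63,80,170,185,,thigh smartphone 50 Hz ±16 g; wrist smartwatch 157 Hz ±2 g
GrazUTOL,2015,waist,accelerometer;orientation,5,,2,2460,2240,220,5,,,,,,,,smartphone in belt bag
UMAFall,2016,ankle;chest;thigh;waist;wrist,accelerometer;gyroscope;magnetometer,100,,16,746,538,208,19,18,68,50,97,156,193,,waist smartphone 100 Hz; satellite IMUs 20 Hz
FARSEEING,2016,waist;thigh,accelerometer;gyroscope,100,,6,22,0,22,15,56,86,51,101,148,190,,real-world falls of older adults
SisFall,2017,waist,accelerometer;gyroscope,200,,16,4505,2707,1798,38,19,75,41.5,102,149,183,,secondary accelerometer ±8 g
UniMiB-SHAR,2017,thigh,accelerometer,50,,2,7013,5314,1699,30,18,60,50,82,160,190,,smartphone in trouser pocket
SMotion,2017,waist,accelerometer;gyroscope,51,,4,309,304,5,120,17,79,35,95,125,186,,aimed at fall-risk assessment; only 5 falls
IMUFD,2017,chest;head;ankle;thigh;waist,accelerometer;gyroscope;magnetometer,128,,16,600,390,210,10,,,,,,,,seven external IMUs
CGU-BES,2018,chest,accelerometer;gyroscope,200,,3.6,195,135,60,15,,,,,,,,age 21.8 +/- 1.8 years
CMDFall,2018,wrist;hip,accelerometer,50,,16,1000,600,400,50,21,40,,,,,,left wrist and left hip; also cameras (out of scope)
DU-MD,2018,wrist,accelerometer,33,,4,3299,2309,990,10,16,22,40,101,147,185,,
SmartFall,2018,wrist,accelerometer,31.25,,16,181,90,91,7,21,55,,,,,smartfall-smartwatch,released jointly with Smartwatch
Smartwatch,2018,wrist,accelerometer,31.25,,8,2563,2456,107,7,20,35,,,,,smartfall-smartwatch,released jointly with SmartFall; MS Band
UP-Fall,2019,ankle;neck;thigh;waist;wrist,accelerometer;gyroscope,14,,8,559,304,255,17,18,24,53,99,157,175,,five external IMUs; also cameras (out of scope)
DOFDA,2019,waist,accelerometer;gyroscope;orientation;magnetometer,33,,16,432,120,312,8,22,29,60,94,173,187,,
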