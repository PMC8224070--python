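year,event,predicted,observed
2010,first migration,2010-04-30,2010-05-06
2011,first migration,2011-04-16,2011-04-14
2012,first migration,2012-04-29,NA
2013,first migration,2013-05-07,2013-05-27
2014,first migration,2014-04-07,2014-04-09
2015,first migration,2015-05-02,2015-04-21
2016,first migration,2016-05-03,2016-05-09
2017,first migration,2017-04-18,2017-04-25
2018,first migration,2018-04-20,2018-04-20
2019,first migration,2019-04-19,2019-04-16
2020,first migration,2020-04-09,2020-04-09
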