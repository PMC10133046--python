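import pytest

from noticelink.records_io import DeviceRecord, NoticeRecord


@pytest.fixture
def six_device_registry():
    """Small registry with a duplicate registration and varied codes."""
    return [
        DeviceRecord("101", "Acme Medical Srl", "AC-100", "Alpha Monitor", "MD", "Z110401"),
        DeviceRecord("102", "Acme Medical Srl", "AC-200", "Beta Scanner", "MD", "Z110402"),
        DeviceRecord("103", "Beta Devices", "BD-1", "Gamma Probe", "MD", "Z120101"),
        DeviceRecord("104", "Gamma Corp", "GC-7", "Delta Implant", "MD", "P0908"),
        DeviceRecord("105", "Acme Medical Srl", "AC-100", "Alpha Monitor", "MD", "Z110401"),
        DeviceRecord("106", "Delta Inc", "DI-9", "Epsilon Pump", "MD", "A0101"),
    ]


@pytest.fixture
def make_notice():
    def _make(ref="SN-000001", manufacturer="Acme Medical Srl",
              device="Alpha Monitor", commercial_name="Alpha Monitor AC-100",
              bdrmd=None, **kwargs):
        return NoticeRecord(
            reference_number=ref,
            manufacturer=manufacturer,
            device=device,
            commercial_name=commercial_name,
            bdrmd=bdrmd,
            **kwargs,
        )
    return _make
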